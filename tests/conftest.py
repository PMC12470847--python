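import numpy as np
import pytest
from hypothesis import settings

from sfprf.hrf import hrf_kernel
from sfprf.prf import DesignMatrices, GridPredictions, make_search_grid
from sfprf.stimulus import build_run_apertures

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def apertures():
    """Default full-run aperture sequence (330 frames, 0.1° grid)."""
    return build_run_apertures()


@pytest.fixture(scope="session")
def kernel():
    return hrf_kernel()


@pytest.fixture(scope="session")
def fine_engine(apertures, kernel):
    """Design matrices + coarse-grid predictions at the native 0.1° grid."""
    design = DesignMatrices(apertures, kernel)
    preds = GridPredictions(design, make_search_grid())
    return design, preds


@pytest.fixture(scope="session")
def coarse_engine(apertures, kernel):
    """Same, on the factor-2 coarsened grid used for batch fitting."""
    coarse = apertures.coarsen(2)
    design = DesignMatrices(coarse, kernel)
    preds = GridPredictions(design, make_search_grid())
    return design, preds


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
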