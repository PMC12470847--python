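"""pRF forward model and coarse-to-fine fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st_
from scipy import stats
from sklearn.base import clone

from sfprf.hrf import HRFSpec, hrf_kernel
from sfprf.prf import (
    DesignMatrices,
    GridPredictions,
    PRFParams,
    PRFRegressor,
    fit_amplitude_baseline,
    fit_vertex,
    fit_vertices,
    grid_stage,
    make_search_grid,
    predict_bold,
    predict_neural,
    refine_stage,
)
from sfprf.stimulus import ApertureSequence, FieldGrid


def _strip_apertures(grid=None, lo=2.7, hi=3.3):
    """One vertical-strip frame plus an empty and a full-field frame."""
    grid = grid or FieldGrid()
    xx, _ = grid.mesh()
    strip = ((xx >= lo) & (xx <= hi)).astype(np.uint8)
    frames = np.stack([np.zeros_like(strip), np.ones_like(strip), strip])
    return ApertureSequence(
        grid=grid, frames=frames, annotations=["blank"] * 3, tr=1.0
    )


class TestHRF:
    def test_peaks_at_stated_delay_and_causal(self, kernel):
        assert np.argmax(kernel) == 6
        assert kernel[0] == pytest.approx(0.0, abs=1e-6)
        assert kernel.max() == 1.0

    def test_matches_direct_gamma_formula(self):
        # independent oracle: explicit gamma densities via math.gamma
        spec = HRFSpec(peak_delay=5.0, undershoot_delay=14.0, ratio=5.0)
        k = hrf_kernel(spec, duration=30, tr=0.5)
        t = np.arange(0, 30 + 1e-9, 0.5)

        def gpdf(x, a):
            return np.where(
                x > 0, x ** (a - 1) * np.exp(-x) / math.gamma(a), 0.0
            )

        raw = gpdf(t, 6.0) - gpdf(t, 15.0) / 5.0
        assert np.allclose(k, raw / raw.max(), atol=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            HRFSpec(peak_dispersion=0.0)
        with pytest.raises(ValueError):
            hrf_kernel(duration=10)


class TestPredictNeural:
    def test_empty_and_full_field(self):
        ap = _strip_apertures()
        p = predict_neural(PRFParams(1.0, -2.0, 0.7), ap)
        assert p[0] == 0.0
        assert p[1] == pytest.approx(1.0)
        assert np.all((p >= 0) & (p <= 1))

    def test_strip_mass_matches_erf_oracle(self):
        # Gaussian at (3, 0), σ=0.5 under a strip x ∈ [2.7, 3.3]: the overlap
        # is the 1-D Gaussian mass of the strip (the y-axis fully covered)
        ap = _strip_apertures()
        p = predict_neural(PRFParams(3.0, 0.0, 0.5), ap)
        expect = stats.norm.cdf(0.3, scale=0.5) - stats.norm.cdf(-0.3, scale=0.5)
        assert p[2] == pytest.approx(expect, rel=0.01)

    def test_monotone_under_aperture_growth(self, apertures, rng):
        grown = apertures.frames.copy()
        extra = rng.random(grown.shape[1:]) < 0.05
        grown = np.maximum(grown, extra.astype(np.uint8))
        ap2 = ApertureSequence(
            grid=apertures.grid,
            frames=grown,
            annotations=apertures.annotations,
            tr=1.0,
        )
        params = PRFParams(2.0, 1.0, 0.8)
        assert np.all(
            predict_neural(params, ap2) >= predict_neural(params, apertures) - 1e-12
        )

    def test_central_prf_sweep_reversal_symmetry(self, apertures):
        # for a pRF at fixation, the opposite sweep retraces the response
        p = predict_neural(PRFParams(0.0, 0.0, 1.0), apertures)
        ann = apertures.annotations
        for k in (0, 1):
            fwd = [p[i] for i, a in enumerate(ann) if a.startswith(f"bar:{k}:")]
            rev = [p[i] for i, a in enumerate(ann) if a.startswith(f"bar:{k + 4}:")]
            assert np.allclose(fwd, rev[::-1], atol=1e-9)

    def test_sigma_must_be_positive(self, apertures):
        with pytest.raises(ValueError):
            predict_neural(PRFParams(0, 0, 0.0), apertures)


class TestPredictBold:
    def test_impulse_hrf_is_identity(self, apertures):
        params = PRFParams(1.5, 0.5, 0.6)
        neural = predict_neural(params, apertures)
        impulse = np.zeros(8)
        impulse[0] = 1.0
        bold = predict_bold(params, apertures, impulse, restrict=False)
        assert np.allclose(bold, neural)

    def test_linearity(self, apertures, kernel):
        p1 = predict_bold(PRFParams(2, 0, 0.5), apertures, kernel)
        p2 = predict_bold(PRFParams(2, 0, 0.5), apertures, 2 * kernel)
        assert np.allclose(p2, 2 * p1)


class TestGridStage:
    def test_matches_exhaustive_brute_force(self, apertures, kernel):
        # oracle: an independent loop over the same candidates
        design = DesignMatrices(apertures, kernel)
        small = make_search_grid(n_ecc=3, max_ecc=6, n_angles=4, n_sigmas=4)
        preds = GridPredictions(design, small)
        rng = np.random.default_rng(3)
        y = predict_bold(PRFParams(2.3, 1.1, 0.9), apertures, kernel)
        y = y + rng.normal(0, 0.05, y.shape)
        best, r = grid_stage(y, preds)
        rs = []
        for x0, y0, s in small:
            pred = predict_bold(PRFParams(x0, y0, s), apertures, kernel)
            if pred.std() < 1e-12:
                rs.append(-np.inf)
            else:
                rs.append(np.corrcoef(y, pred)[0, 1])
        i = int(np.argmax(rs))
        assert (best.x0, best.y0, best.sigma) == tuple(small[i])
        assert r == pytest.approx(rs[i], abs=1e-5)

    def test_self_consistency_on_grid(self, apertures, kernel, fine_engine):
        design, preds = fine_engine
        cell = preds.params[1234]
        y = predict_bold(PRFParams(*cell), apertures, kernel)
        best, r = grid_stage(y, design and preds)
        assert np.allclose([best.x0, best.y0, best.sigma], cell)
        assert r == pytest.approx(1.0, abs=1e-5)

    def test_constant_series_rejected(self, fine_engine):
        with pytest.raises(ValueError):
            grid_stage(np.ones(250), fine_engine[1])

    @given(a=st_.floats(0.1, 10), b=st_.floats(-5, 5))
    def test_objective_affine_invariant(self, coarse_engine, a, b):
        design, preds = coarse_engine
        rng = np.random.default_rng(7)
        y = rng.normal(size=250)
        p1, r1 = grid_stage(y, preds)
        p2, r2 = grid_stage(a * y + b, preds)
        assert (p1.x0, p1.y0, p1.sigma) == (p2.x0, p2.y0, p2.sigma)
        assert r1 == pytest.approx(r2, abs=1e-4)


class TestRefineStage:
    def test_stationary_at_truth(self, apertures, kernel, fine_engine):
        design, _ = fine_engine
        truth = PRFParams(2.0, -1.0, 0.7)
        y = predict_bold(truth, apertures, kernel)
        params, r, fallback = refine_stage(y, design, truth)
        assert not fallback
        assert r >= 1 - 1e-6
        assert abs(params.x0 - truth.x0) < 0.01
        assert abs(params.sigma - truth.sigma) < 0.01

    def test_white_noise_does_not_crash(self, fine_engine, rng):
        design, preds = fine_engine
        y = rng.normal(size=250)
        init, r0 = grid_stage(y, preds)
        params, r, _ = refine_stage(y, design, init)
        assert np.isfinite(r) and r >= r0 - 1e-9


class TestAmplitudeBaseline:
    def test_exact_affine_case(self, rng):
        pred = rng.normal(size=100)
        beta, base, r2 = fit_amplitude_baseline(2 * pred + 1, pred)
        assert (beta, base) == pytest.approx((2.0, 1.0))
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_series(self):
        t = np.arange(100)
        beta, base, r2 = fit_amplitude_baseline(np.cos(t), np.sin(t))
        assert abs(beta) < 0.05 and r2 < 0.01

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=60)
        x = rng.normal(size=60)
        beta, base, r2 = fit_amplitude_baseline(y, x)
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert beta == pytest.approx(coef[0], abs=1e-10)
        assert base == pytest.approx(coef[1], abs=1e-10)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_constant_prediction_rejected(self):
        with pytest.raises(ValueError):
            fit_amplitude_baseline(np.arange(5.0), np.ones(5))


class TestFitVertex:
    def test_recovers_off_grid_truth(self, apertures, kernel, fine_engine):
        design, preds = fine_engine
        truth = PRFParams(3.17, -2.41, 1.23)  # deliberately off every grid cell
        y = predict_bold(truth, apertures, kernel)
        y = (y - y.mean()) / y.std()  # as the pipeline's z-scored input
        fit = fit_vertex(y, design, preds)
        assert fit.flag == "ok"
        assert abs(fit.params.x0 - truth.x0) < 0.05
        assert abs(fit.params.y0 - truth.y0) < 0.05
        assert abs(fit.params.sigma - truth.sigma) < 0.05
        assert fit.r2 > 0.999
        assert fit.beta == pytest.approx(1.0, abs=0.01)  # z-scored prediction

    def test_no_hidden_state(self, apertures, kernel, fine_engine):
        design, preds = fine_engine
        y = predict_bold(PRFParams(1, 1, 0.5), apertures, kernel)
        a = fit_vertex(y, design, preds)
        b = fit_vertex(y, design, preds)
        assert a == b

    def test_truth_outside_aperture_flagged_not_crashed(
        self, apertures, kernel, fine_engine
    ):
        design, preds = fine_engine
        y = predict_bold(PRFParams(9.5, 3.0, 0.5), apertures, kernel)
        if y.std() < 1e-10:
            return  # fully occluded: nothing to fit
        fit = fit_vertex(y, design, preds)
        assert np.isfinite(fit.params.sigma)

    def test_constant_series_returns_failed_fit(self, fine_engine):
        design, preds = fine_engine
        fit = fit_vertex(np.zeros(250), design, preds)
        assert fit.flag.startswith("failed")
        assert fit.r2 == 0.0

    def test_batch_wrapper_columns(self, apertures):
        y = predict_bold(PRFParams(2, 0, 0.8), apertures, hrf_kernel())
        table = fit_vertices(
            np.vstack([y, y]), apertures, condition="high_adapted"
        )
        assert list(table["vertex_id"]) == [0, 1]
        assert (table["condition"] == "high_adapted").all()
        assert table.loc[0, "sigma_deg"] == pytest.approx(0.8, abs=0.05)


class TestPRFRegressor:
    def test_sklearn_contract(self):
        est = PRFRegressor(n_sigmas=8)
        params = est.get_params()
        assert params["n_sigmas"] == 8
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_and_predict(self, apertures, kernel):
        truth = PRFParams(2.5, 1.5, 0.9)
        y = predict_bold(truth, apertures, kernel)
        est = PRFRegressor().fit(apertures, y)
        assert est.sigma_ == pytest.approx(0.9, abs=0.05)
        assert est.ecc_ == pytest.approx(truth.eccentricity, abs=0.1)
        pred = est.predict(apertures)
        assert pred.shape == y.shape
        assert np.corrcoef(pred, y)[0, 1] > 0.999

    def test_predict_before_fit_raises(self, apertures):
        with pytest.raises(AttributeError):
            PRFRegressor().predict(apertures)
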