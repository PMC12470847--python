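"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFSpec", "hrf_kernel", "convolve_hrf"]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF parameters (seconds).

    The kernel is the difference of two gamma densities; each lobe is
    parametrized so that its mode equals the stated delay (shape =
    1 + delay/dispersion, scale = dispersion).  The undershoot is scaled by
    ``1/ratio`` relative to the peak lobe before peak-normalization.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("delays must be positive")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def hrf_kernel(
    spec: HRFSpec = HRFSpec(), duration: float = 32.0, tr: float = 1.0
) -> np.ndarray:
    """Sample the double-gamma HRF at the TR grid, peak-normalized to 1.

    Causal: the kernel is zero at t=0 and defined for t in [0, duration].
    """
    if duration < 20:
        raise ValueError("duration must cover the HRF (>= 20 s)")
    t = np.arange(0, duration + 1e-9, tr)
    peak = stats.gamma.pdf(
        t, a=1 + spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        a=1 + spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - under / spec.ratio
    return h / h.max()


def convolve_hrf(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the input length.

    Works on 1-D series or on (T, k) column stacks (each column convolved).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        return np.convolve(series, kernel)[: series.shape[0]]
    out = np.empty_like(series)
    for j in range(series.shape[1]):
        out[:, j] = np.convolve(series[:, j], kernel)[: series.shape[0]]
    return out
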