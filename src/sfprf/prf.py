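"""2D-Gaussian population receptive field model and coarse-to-fine fitting.

The forward model: a voxel's neural response at each volume is the overlap of
an isotropic 2D Gaussian (centre ``x0, y0``, SD ``sigma``) with the binary
stimulus aperture, normalized by the Gaussian's total mass on the grid.  The
predicted BOLD series is this overlap series convolved with a canonical HRF
and restricted to the mapping volumes.

Fitting maximizes the Pearson correlation between predicted and observed
series in two stages: an exhaustive search over a coarse parameter grid, then
Nelder-Mead refinement from the best grid cell.  Response amplitude (beta)
and baseline are estimated afterwards by ordinary least squares.

:class:`PRFRegressor` packages the procedure as a scikit-learn style
estimator; :func:`fit_vertex` / :func:`fit_vertices` are the functional
equivalents, with shared precomputation across vertices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal
from sklearn.base import BaseEstimator, RegressorMixin

from .hrf import HRFSpec, hrf_kernel
from .stimulus import ApertureSequence

__all__ = [
    "PRFParams",
    "PRFFit",
    "make_search_grid",
    "DesignMatrices",
    "GridPredictions",
    "predict_neural",
    "predict_bold",
    "grid_stage",
    "refine_stage",
    "fit_amplitude_baseline",
    "fit_vertex",
    "fit_vertices",
    "PRFRegressor",
]

FIT_COLUMNS = [
    "vertex_id",
    "condition",
    "x0_deg",
    "y0_deg",
    "sigma_deg",
    "beta",
    "baseline",
    "r2",
    "ecc_deg",
    "polar_rad",
    "flag",
]


@dataclass(frozen=True)
class PRFParams:
    x0: float
    y0: float
    sigma: float

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x0, self.y0)

    @property
    def polar_angle(self) -> float:
        return math.atan2(self.y0, self.x0)


@dataclass
class PRFFit:
    """One vertex/condition fit: Gaussian parameters plus regression terms."""

    params: PRFParams
    beta: float
    baseline: float
    r2: float
    correlation: float
    flag: str = "ok"

    def as_row(self, vertex_id=None, condition=None) -> dict:
        return {
            "vertex_id": vertex_id,
            "condition": condition,
            "x0_deg": self.params.x0,
            "y0_deg": self.params.y0,
            "sigma_deg": self.params.sigma,
            "beta": self.beta,
            "baseline": self.baseline,
            "r2": self.r2,
            "ecc_deg": self.params.eccentricity,
            "polar_rad": self.params.polar_angle,
            "flag": self.flag,
        }


def make_search_grid(
    n_ecc: int = 12,
    max_ecc: float = 9.0,
    n_angles: int = 24,
    n_sigmas: int = 16,
    sigma_min: float = 0.1,
    sigma_max: float = 4.0,
) -> np.ndarray:
    """Coarse-stage candidates: (N, 3) array of (x0, y0, sigma).

    Polar positions (linear eccentricities 0..max_ecc crossed with evenly
    spaced angles; the origin appears once) crossed with log-spaced sigmas.
    """
    if min(n_ecc, n_angles, n_sigmas) < 1 or sigma_min <= 0:
        raise ValueError("grid dimensions must be >= 1 and sigma_min > 0")
    eccs = np.linspace(0.0, max_ecc, n_ecc)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    positions = [(0.0, 0.0)] if eccs[0] == 0 else []
    for e in eccs[eccs > 0]:
        for a in angles:
            positions.append((e * math.cos(a), e * math.sin(a)))
    sigmas = np.geomspace(sigma_min, sigma_max, n_sigmas)
    cells = [(x, y, s) for (x, y) in positions for s in sigmas]
    return np.asarray(cells, dtype=float)


class DesignMatrices:
    """Flattened aperture frames and their HRF-convolved, mapping-restricted
    counterpart, shared across all vertices fit against one run design."""

    def __init__(self, apertures: ApertureSequence, kernel: np.ndarray):
        grid = apertures.grid
        xx, yy = grid.mesh()
        self.grid = grid
        self.xf = xx.ravel().astype(np.float32)
        self.yf = yy.ravel().astype(np.float32)
        T = apertures.n_frames
        self.F = apertures.frames.reshape(T, -1).astype(np.float32)
        conv = signal.fftconvolve(self.F, kernel[:, None].astype(np.float32), axes=0)
        self.mapping_idx = apertures.mapping_indices()
        if self.mapping_idx.size == 0:  # no annotated mapping volumes: use all
            self.mapping_idx = np.arange(T)
        self.Fc_map = np.ascontiguousarray(conv[: T][self.mapping_idx])
        self.n_volumes = T

    def gaussian(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        s2 = 2.0 * sigma * sigma
        return np.exp(-((self.xf - x0) ** 2 + (self.yf - y0) ** 2) / s2)

    def predict_map(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        """HRF-convolved prediction at mapping volumes, normalized overlap."""
        g = self.gaussian(x0, y0, sigma)
        return (self.Fc_map @ g) / g.sum()


class GridPredictions:
    """Z-scored coarse-grid predictions, built once per design and reused."""

    def __init__(
        self, design: DesignMatrices, grid: np.ndarray, batch: int = 256
    ):
        self.params = np.asarray(grid, dtype=float)
        n = self.params.shape[0]
        M = design.Fc_map.shape[0]
        Z = np.empty((n, M), dtype=np.float32)
        valid = np.ones(n, dtype=bool)
        for i in range(0, n, batch):
            chunk = self.params[i : i + batch].astype(np.float32)
            G = np.exp(
                -(
                    (design.xf[:, None] - chunk[:, 0]) ** 2
                    + (design.yf[:, None] - chunk[:, 1]) ** 2
                )
                / (2.0 * chunk[:, 2] ** 2)
            )
            P = (design.Fc_map @ G).T  # (batch, M)
            P -= P.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(P, axis=1)
            bad = norms < 1e-12
            norms[bad] = 1.0
            valid[i : i + batch] = ~bad
            Z[i : i + batch] = P / norms[:, None]
        self.Z = Z
        self.valid = valid


def predict_neural(params: PRFParams, apertures: ApertureSequence) -> np.ndarray:
    """Normalized Gaussian-aperture overlap at every volume; values in [0, 1]."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    xx, yy = apertures.grid.mesh()
    g = np.exp(
        -((xx - params.x0) ** 2 + (yy - params.y0) ** 2) / (2 * params.sigma**2)
    )
    gf = g.ravel()
    F = apertures.frames.reshape(apertures.n_frames, -1)
    return (F @ gf) / gf.sum()


def predict_bold(
    params: PRFParams,
    apertures: ApertureSequence,
    kernel: np.ndarray,
    restrict: bool = True,
) -> np.ndarray:
    """Causal HRF convolution of the neural prediction, truncated to the run.

    With ``restrict`` the series is cropped to the mapping volumes (the
    samples actually used for fitting); convolution is always computed on the
    full run so HRF spillover across blank boundaries is modelled.
    """
    neural = predict_neural(params, apertures)
    bold = np.convolve(neural, kernel)[: neural.shape[0]]
    if restrict:
        idx = apertures.mapping_indices()
        if idx.size:
            bold = bold[idx]
    return bold


def _prepare_observed(y: np.ndarray, design: DesignMatrices) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] == design.n_volumes:
        y = y[design.mapping_idx]
    elif y.shape[0] != design.Fc_map.shape[0]:
        raise ValueError(
            f"observed length {y.shape[0]} matches neither the full run "
            f"({design.n_volumes}) nor the mapping sequence "
            f"({design.Fc_map.shape[0]})"
        )
    return y


def grid_stage(
    observed: np.ndarray, preds: GridPredictions
) -> tuple[PRFParams, float]:
    """Exhaustive coarse search: best-correlating grid cell.

    Zero-variance predictions are treated as correlation −inf; ties break to
    the first cell in deterministic grid order.
    """
    o = np.asarray(observed, dtype=np.float32)
    o = o - o.mean()
    norm = np.linalg.norm(o)
    if norm < 1e-12:
        raise ValueError("observed series is constant")
    o /= norm
    r = preds.Z @ o
    r[~preds.valid] = -np.inf
    best = int(np.argmax(r))
    x0, y0, s = preds.params[best]
    return PRFParams(x0, y0, s), float(r[best])


def refine_stage(
    observed: np.ndarray,
    design: DesignMatrices,
    init: PRFParams,
    xatol: float = 1e-4,
    fatol: float = 1e-4,
    maxiter: int = 500,
) -> tuple[PRFParams, float, bool]:
    """Nelder-Mead maximization of the correlation from the grid optimum.

    Returns (params, correlation, fallback) where ``fallback`` marks an
    optimizer result no better than the start (the start is then returned).
    """
    o = np.asarray(observed, dtype=np.float32)
    o = o - o.mean()
    norm = np.linalg.norm(o)
    if norm < 1e-12:
        raise ValueError("observed series is constant")
    o /= norm
    Fc = design.Fc_map
    xf, yf = design.xf, design.yf

    def neg_corr(theta: np.ndarray) -> float:
        x0, y0, s = (float(v) for v in theta)  # keep float32 arithmetic
        if s == 0.0:
            return 1.0
        g = np.exp(-((xf - x0) ** 2 + (yf - y0) ** 2) / (2.0 * s * s))
        p = Fc @ g
        p = p - p.mean()
        n = np.linalg.norm(p)
        if not np.isfinite(n) or n < 1e-12:
            return 1.0
        return -float(o @ p) / n

    x0 = np.array([init.x0, init.y0, init.sigma], dtype=float)
    # simplex steps on the scale of the coarse grid spacing
    steps = np.array([0.3, 0.3, max(0.3 * abs(init.sigma), 0.05)])
    simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(3)[i] for i in range(3)])
    res = optimize.minimize(
        neg_corr,
        x0,
        method="Nelder-Mead",
        options=dict(
            xatol=xatol,
            fatol=fatol,
            maxiter=maxiter,
            initial_simplex=simplex,
        ),
    )
    r_init = -neg_corr(x0)
    r_ref = -float(res.fun)
    if np.isfinite(r_ref) and r_ref >= r_init:
        return PRFParams(*res.x), r_ref, False
    return init, r_init, True


def fit_amplitude_baseline(
    observed: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """OLS of observed on predicted: (beta, baseline, r² = squared Pearson r)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    pv = predicted - predicted.mean()
    ss = pv @ pv
    if ss < 1e-300:
        raise ValueError("predicted series is constant")
    beta = float(pv @ (observed - observed.mean()) / ss)
    baseline = float(observed.mean() - beta * predicted.mean())
    denom = math.sqrt(ss * ((observed - observed.mean()) @ (observed - observed.mean())))
    r = 0.0 if denom < 1e-300 else float(pv @ (observed - observed.mean()) / denom)
    return beta, baseline, r * r


def fit_vertex(
    observed: np.ndarray,
    design: DesignMatrices,
    preds: GridPredictions,
    xatol: float = 1e-4,
    fatol: float = 1e-4,
    maxiter: int = 500,
    standardize_prediction: bool = True,
) -> PRFFit:
    """Coarse-to-fine fit of one vertex's (averaged, z-scored) series.

    The prediction used for the amplitude/baseline regression is z-scored by
    default, so beta is expressed in units of observed-series SD (and a good
    fit of a z-scored series yields beta ≈ correlation).  Failures return a
    flagged fit with r² = 0 instead of raising.
    """
    try:
        y = _prepare_observed(observed, design)
        init, r_grid = grid_stage(y, preds)
        params, r, fallback = refine_stage(
            y, design, init, xatol=xatol, fatol=fatol, maxiter=maxiter
        )
        pred = design.predict_map(params.x0, params.y0, params.sigma)
        if standardize_prediction:
            sd = pred.std()
            if sd > 1e-12:
                pred = (pred - pred.mean()) / sd
        beta, baseline, r2 = fit_amplitude_baseline(y, pred)
        flag = "refine_fallback" if fallback else "ok"
        return PRFFit(params, beta, baseline, r2, r, flag)
    except ValueError as err:
        return PRFFit(PRFParams(0.0, 0.0, 0.0), 0.0, 0.0, 0.0, 0.0, f"failed:{err}")


def fit_vertices(
    Y: np.ndarray,
    apertures: ApertureSequence,
    hrf: HRFSpec = HRFSpec(),
    search_grid: np.ndarray | None = None,
    vertex_ids=None,
    condition=None,
    **options,
) -> pd.DataFrame:
    """Fit a batch of vertices against one aperture sequence.

    ``Y`` is (n_vertices, T) with T either the full run or the mapping-only
    length.  Grid predictions are computed once and shared.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    kernel = hrf_kernel(hrf, tr=apertures.tr)
    design = DesignMatrices(apertures, kernel)
    grid = make_search_grid() if search_grid is None else search_grid
    preds = GridPredictions(design, grid)
    if vertex_ids is None:
        vertex_ids = np.arange(Y.shape[0])
    rows = []
    for i in range(Y.shape[0]):
        fit = fit_vertex(Y[i], design, preds, **options)
        rows.append(fit.as_row(vertex_id=vertex_ids[i], condition=condition))
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


class PRFRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for a single vertex's pRF.

    ``fit(X, y)`` takes an :class:`ApertureSequence` as ``X`` (the stimulus
    design) and the observed BOLD series as ``y``; fitted attributes are
    ``x0_``, ``y0_``, ``sigma_``, ``beta_``, ``baseline_``, ``r2_``,
    ``correlation_``, ``ecc_``, ``polar_`` and ``flag_``.  ``predict(X)``
    returns the fitted model's BOLD prediction (amplitude/baseline applied).

    Parameters mirror the coarse grid (counts/ranges) and the Nelder-Mead
    tolerances; see :func:`make_search_grid`.
    """

    def __init__(
        self,
        hrf: HRFSpec = HRFSpec(),
        n_ecc: int = 12,
        max_ecc: float = 9.0,
        n_angles: int = 24,
        n_sigmas: int = 16,
        sigma_min: float = 0.1,
        sigma_max: float = 4.0,
        xatol: float = 1e-4,
        fatol: float = 1e-4,
        maxiter: int = 500,
    ):
        self.hrf = hrf
        self.n_ecc = n_ecc
        self.max_ecc = max_ecc
        self.n_angles = n_angles
        self.n_sigmas = n_sigmas
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    def _search_grid(self) -> np.ndarray:
        return make_search_grid(
            self.n_ecc,
            self.max_ecc,
            self.n_angles,
            self.n_sigmas,
            self.sigma_min,
            self.sigma_max,
        )

    def fit(self, X: ApertureSequence, y: np.ndarray) -> "PRFRegressor":
        kernel = hrf_kernel(self.hrf, tr=X.tr)
        design = DesignMatrices(X, kernel)
        preds = GridPredictions(design, self._search_grid())
        fit = fit_vertex(
            y, design, preds, xatol=self.xatol, fatol=self.fatol, maxiter=self.maxiter
        )
        self.x0_ = fit.params.x0
        self.y0_ = fit.params.y0
        self.sigma_ = fit.params.sigma
        self.beta_ = fit.beta
        self.baseline_ = fit.baseline
        self.r2_ = fit.r2
        self.correlation_ = fit.correlation
        self.ecc_ = fit.params.eccentricity
        self.polar_ = fit.params.polar_angle
        self.flag_ = fit.flag
        return self

    def predict(self, X: ApertureSequence) -> np.ndarray:
        if not hasattr(self, "sigma_"):
            raise AttributeError("PRFRegressor is not fitted")
        kernel = hrf_kernel(self.hrf, tr=X.tr)
        pred = predict_bold(
            PRFParams(self.x0_, self.y0_, max(self.sigma_, 1e-6)), X, kernel
        )
        sd = pred.std()
        if sd > 1e-12:
            pred = (pred - pred.mean()) / sd
        return self.beta_ * pred + self.baseline_
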