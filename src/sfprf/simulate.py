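"""Ground-truthed synthetic data: adapted neural populations, BOLD runs, and
a simulated 2AFC observer.

The generative hypothesis: a voxel/vertex pools many neural subunits whose
receptive field size is inversely linked to their preferred spatial frequency
(pref_sf · rf_size = c).  Adapting to a high/low SF suppresses the gain of
subunits tuned near the adapter, so the aggregate — what a pRF fit sees — is
dominated by the unadapted subunits: a high-SF adapter silences small-RF
subunits and the effective pRF grows; a low-SF adapter does the opposite.

Every simulated vertex carries its ground-truth effective pRF size per
condition (the best-fitting single Gaussian to the gain-weighted aggregate),
so downstream estimation can be judged against a known oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .hrf import HRFSpec, hrf_kernel
from .stimulus import ApertureSequence, FieldGrid

__all__ = [
    "NeuralSubunit",
    "NeuralPopulation",
    "AdaptationModel",
    "PopulationConfig",
    "VertexTimeSeries",
    "ObserverModel",
    "FMRISimConfig",
    "FMRIDataset",
    "adaptation_gain",
    "sample_population",
    "effective_prf_oracle",
    "effective_sigma_oracle",
    "subunit_overlaps",
    "neural_timecourse",
    "bold_from_neural",
    "noise_sd_for_reliability",
    "simulate_fmri_dataset",
    "simulate_observer_response",
]

#: Adapter spatial frequencies (cpd) by condition label.
ADAPTER_SF = {"high_adapted": 3.5, "low_adapted": 0.5}


@dataclass(frozen=True)
class NeuralSubunit:
    """One subunit: RF centre/size plus SF preference and resting gain."""

    x: float
    y: float
    rf_size: float  # Gaussian SD, deg
    pref_sf: float  # cpd
    base_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.rf_size <= 0 or self.pref_sf <= 0:
            raise ValueError("rf_size and pref_sf must be positive")


@dataclass
class NeuralPopulation:
    """A vertex's subunits around a nominal visual-field position."""

    vertex_id: int
    ecc: float
    angle: float  # polar angle, rad
    subunits: list[NeuralSubunit]
    truth_sigma: dict = field(default_factory=dict)  # condition -> oracle SD

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("population needs at least one subunit")

    @property
    def nominal_xy(self) -> tuple[float, float]:
        return (self.ecc * math.cos(self.angle), self.ecc * math.sin(self.angle))

    def gains(self, condition: str, model: "AdaptationModel") -> np.ndarray:
        sf = ADAPTER_SF[condition]
        return np.array(
            [
                u.base_gain * adaptation_gain(u.pref_sf, sf, model)
                for u in self.subunits
            ]
        )


@dataclass(frozen=True)
class AdaptationModel:
    """Gaussian gain suppression in octave (log2-SF) space.

    gain = 1 − A·exp(−d²/(2w²)) with d the octave distance from the adapter;
    A is the suppression at the adapter SF, w the bandwidth in octaves.  The
    1.3 cpd mapping SF sits ~1.4 octaves from both adapters, inside the ≤2
    octave range over which SF adaptation measurably transfers.
    """

    suppression: float = 0.5
    bandwidth_octaves: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.suppression < 1):
            raise ValueError("suppression must be in [0, 1)")
        if self.bandwidth_octaves <= 0:
            raise ValueError("bandwidth must be positive")


def adaptation_gain(
    pref_sf: float, adapter_sf: float, model: AdaptationModel
) -> float:
    """Multiplicative gain of a subunit after adaptation; in [1−A, 1]."""
    if pref_sf <= 0 or adapter_sf <= 0:
        raise ValueError("spatial frequencies must be positive")
    d = math.log2(pref_sf / adapter_sf)
    return 1.0 - model.suppression * math.exp(
        -(d * d) / (2.0 * model.bandwidth_octaves**2)
    )


@dataclass(frozen=True)
class PopulationConfig:
    """Subunit sampling rules.

    RF sizes are log-normal with median ``size_intercept + size_slope·ecc``
    (a V1-like eccentricity scaling) and log-SD ``size_log_sd``; centres
    scatter isotropically with SD ``scatter_coeff ×`` the median size;
    preferred SF follows the scale-invariance rule pref_sf = c / rf_size
    with c chosen so a 0.5° subunit prefers the 1.3 cpd mapping SF.
    """

    n_subunits: int = 8
    size_intercept: float = 0.25  # deg at fixation
    size_slope: float = 0.12  # deg per deg eccentricity
    size_log_sd: float = 0.4
    scatter_coeff: float = 0.5
    sf_size_constant: float = 0.65  # cpd·deg

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("need at least one subunit")
        if self.size_intercept <= 0 or self.size_slope < 0:
            raise ValueError("invalid size scaling")
        if self.size_log_sd < 0 or self.scatter_coeff < 0:
            raise ValueError("spreads must be non-negative")
        if self.sf_size_constant <= 0:
            raise ValueError("sf_size_constant must be positive")


def sample_population(
    nominal_ecc: float,
    nominal_angle: float,
    cfg: PopulationConfig,
    rng: np.random.Generator,
    vertex_id: int = 0,
) -> NeuralPopulation:
    """Draw one vertex's subunits around a nominal position."""
    median = cfg.size_intercept + cfg.size_slope * nominal_ecc
    sizes = np.exp(rng.normal(math.log(median), cfg.size_log_sd, cfg.n_subunits))
    cx = nominal_ecc * math.cos(nominal_angle)
    cy = nominal_ecc * math.sin(nominal_angle)
    scatter = cfg.scatter_coeff * median
    xs = rng.normal(cx, scatter, cfg.n_subunits)
    ys = rng.normal(cy, scatter, cfg.n_subunits)
    subunits = [
        NeuralSubunit(
            x=float(xs[i]),
            y=float(ys[i]),
            rf_size=float(sizes[i]),
            pref_sf=cfg.sf_size_constant / float(sizes[i]),
        )
        for i in range(cfg.n_subunits)
    ]
    return NeuralPopulation(
        vertex_id=vertex_id, ecc=nominal_ecc, angle=nominal_angle, subunits=subunits
    )


def _aggregate_profile(
    pop: NeuralPopulation, gains: np.ndarray, xf: np.ndarray, yf: np.ndarray
) -> np.ndarray:
    """Gain-weighted sum of mass-normalized subunit Gaussians on flat coords.

    Mass normalization matches the response model: each subunit's overlap is
    divided by its total mass, so its contribution to the aggregate profile
    carries weight g_i regardless of RF size.
    """
    out = np.zeros_like(xf, dtype=float)
    for g, u in zip(gains, pop.subunits):
        if g == 0:
            continue
        prof = np.exp(-((xf - u.x) ** 2 + (yf - u.y) ** 2) / (2 * u.rf_size**2))
        s = prof.sum()
        if s > 0:
            out += g * prof / s
    return out


def effective_prf_oracle(
    pop: NeuralPopulation,
    condition: str,
    model: AdaptationModel,
    grid: FieldGrid = FieldGrid(),
) -> tuple[float, float, float]:
    """Ground truth: (x0, y0, sigma) of the best single Gaussian (least
    squares on the grid, amplitude profiled out) for the adapted aggregate."""
    gains = pop.gains(condition, model)
    if np.all(gains == 0):
        raise ValueError("all subunit gains are zero")
    xx, yy = grid.mesh()
    xf, yf = xx.ravel(), yy.ravel()
    # restrict to a window around the population for speed
    cx = np.array([u.x for u in pop.subunits])
    cy = np.array([u.y for u in pop.subunits])
    smax = max(u.rf_size for u in pop.subunits)
    pad = 4.0 * smax
    sel = (
        (xf >= cx.min() - pad)
        & (xf <= cx.max() + pad)
        & (yf >= cy.min() - pad)
        & (yf <= cy.max() + pad)
    )
    xf, yf = xf[sel], yf[sel]
    target = _aggregate_profile(pop, gains, xf, yf)
    tnorm = target @ target

    def obj(theta: np.ndarray) -> float:
        x0, y0, log_s = theta
        s = math.exp(log_s)
        g = np.exp(-((xf - x0) ** 2 + (yf - y0) ** 2) / (2 * s * s))
        num = g @ target
        den = g @ g
        if den < 1e-300:
            return tnorm
        return tnorm - num * num / den  # residual SS with LS amplitude

    # moment-based start: component masses are proportional to the gains
    w = gains / gains.sum()
    mx = float(w @ cx)
    my = float(w @ cy)
    var = float(
        w @ (np.array([u.rf_size for u in pop.subunits]) ** 2)
        + w @ ((cx - mx) ** 2 + (cy - my) ** 2) / 2
    )
    res = optimize.minimize(
        obj,
        np.array([mx, my, 0.5 * math.log(max(var, 1e-6))]),
        method="Nelder-Mead",
        options=dict(xatol=1e-5, fatol=1e-12, maxiter=400),
    )
    x0, y0, log_s = res.x
    return float(x0), float(y0), float(math.exp(log_s))


def effective_sigma_oracle(
    pop: NeuralPopulation,
    condition: str,
    model: AdaptationModel,
    grid: FieldGrid = FieldGrid(),
) -> float:
    """Ground-truth effective pRF SD for one condition (see
    :func:`effective_prf_oracle`)."""
    return effective_prf_oracle(pop, condition, model, grid)[2]


def subunit_overlaps(
    pop: NeuralPopulation, apertures: ApertureSequence
) -> np.ndarray:
    """(n_subunits, T) mass-normalized overlap of each subunit with each
    frame; rows are condition-independent and reusable across gains."""
    xx, yy = apertures.grid.mesh()
    xf, yf = xx.ravel(), yy.ravel()
    F = apertures.frames.reshape(apertures.n_frames, -1).astype(np.float32)
    out = np.empty((len(pop.subunits), apertures.n_frames))
    for i, u in enumerate(pop.subunits):
        g = np.exp(-((xf - u.x) ** 2 + (yf - u.y) ** 2) / (2 * u.rf_size**2))
        out[i] = (F @ g.astype(np.float32)) / g.sum()
    return out


def neural_timecourse(
    pop: NeuralPopulation,
    condition: str,
    apertures: ApertureSequence,
    model: AdaptationModel,
    overlaps: np.ndarray | None = None,
) -> np.ndarray:
    """Gain-weighted population response r(t) = Σ g_i · overlap_i(t)."""
    if overlaps is None:
        overlaps = subunit_overlaps(pop, apertures)
    gains = pop.gains(condition, model)
    return gains @ overlaps


def bold_from_neural(
    series: np.ndarray,
    kernel: np.ndarray,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One BOLD run: causal HRF convolution, scaled, plus iid Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    series = np.asarray(series, dtype=float)
    y = amplitude * np.convolve(series, kernel)[: series.shape[0]] + baseline
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return y


def noise_sd_for_reliability(
    signal_sd: float, target_r: float, n_runs_per_condition: int
) -> float:
    """Noise SD giving an expected split-half correlation ``target_r``.

    The split correlates the mean of the odd- with the mean of the
    even-indexed runs of a condition (halves of size ⌈k/2⌉ and ⌊k/2⌋).  For
    iid noise, r = v / sqrt((v + u/n1)(v + u/n2)) with v the signal variance
    and u the noise variance; solved for u.
    """
    if not (0 < target_r < 1):
        raise ValueError("target_r must be in (0, 1)")
    if n_runs_per_condition < 2:
        raise ValueError("need at least two runs per condition to split")
    n1 = (n_runs_per_condition + 1) // 2
    n2 = n_runs_per_condition // 2
    v = signal_sd**2
    # quadratic in u: u²/(n1 n2) + v(1/n1 + 1/n2) u + v²(1 − 1/r²) = 0
    a = 1.0 / (n1 * n2)
    b = v * (1.0 / n1 + 1.0 / n2)
    c = v * v * (1.0 - 1.0 / target_r**2)
    u = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    return math.sqrt(u)


@dataclass
class VertexTimeSeries:
    """Multi-run BOLD samples for one vertex under one adapter condition."""

    vertex_id: int
    condition: str
    runs: np.ndarray  # (n_runs, T)
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.runs = np.atleast_2d(np.asarray(self.runs, dtype=float))


@dataclass(frozen=True)
class FMRISimConfig:
    """The simulated experiment: vertices, runs, adaptation, and noise.

    ``n_runs`` counts total mapping runs; they alternate HL/LH adapter
    layouts, so the count must be even for balanced conditions.  ``rois``
    maps an ROI label to its (size_intercept, size_slope) scaling.  Noise is
    calibrated per vertex to ``target_split_half_r`` unless an absolute
    ``noise_sd`` is given.
    """

    n_vertices: int = 300
    n_runs: int = 6
    ecc_range: tuple[float, float] = (0.5, 7.0)
    rois: tuple = (("V1", 0.25, 0.12),)
    adaptation: AdaptationModel = AdaptationModel()
    population: PopulationConfig = PopulationConfig()
    hrf: HRFSpec = HRFSpec()
    amplitude: float = 1.0
    baseline: float = 100.0
    target_split_half_r: float = 0.7
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_runs % 2 != 0 or self.n_runs < 2:
            raise ValueError("n_runs must be even (balanced HL/LH) and >= 2")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.rois:
            raise ValueError("at least one ROI required")


@dataclass
class FMRIDataset:
    """Simulated vertices with per-condition runs and oracle ground truth."""

    truth: pd.DataFrame
    bold: dict  # vertex_id -> {condition: (n_runs/2, T) array}
    populations: list[NeuralPopulation]
    run_labels: list[str]  # 'HL'/'LH' per acquired run
    tr: float = 1.0

    def timeseries(self, vertex_id: int, condition: str) -> VertexTimeSeries:
        return VertexTimeSeries(
            vertex_id, condition, self.bold[vertex_id][condition], tr=self.tr
        )


def _wedge_free_angle(rng: np.random.Generator, hemifield: str) -> float:
    """Polar angle within one hemifield, clear of the meridian wedges (±10°
    around both vertical meridians, with a 2° safety margin)."""
    a = rng.uniform(-math.radians(78), math.radians(78))
    return math.pi - a if hemifield == "left" else a


def simulate_fmri_dataset(
    cfg: FMRISimConfig,
    apertures: ApertureSequence,
    rng: np.random.Generator | int,
) -> FMRIDataset:
    """Generate one participant's dataset for both adapter conditions.

    Runs alternate HL/LH (high-SF adapter left, low right, then swapped); a
    vertex's condition in a given run is the adapter SF in its hemifield, so
    each vertex accrues ``n_runs/2`` runs per condition.  Ground-truth
    effective sigmas (oracle single-Gaussian fits to the adapted aggregate)
    are stored in the ``truth`` table.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    kernel = hrf_kernel(cfg.hrf, tr=apertures.tr)
    run_labels = ["HL" if i % 2 == 0 else "LH" for i in range(cfg.n_runs)]
    half = cfg.n_runs // 2
    lo, hi = cfg.ecc_range

    truth_rows = []
    bold: dict = {}
    populations: list[NeuralPopulation] = []
    roi_list = list(cfg.rois)
    for vid in range(cfg.n_vertices):
        roi_name, a, b = roi_list[vid % len(roi_list)]
        hemifield = "left" if vid % 2 == 0 else "right"
        ecc = rng.uniform(lo, hi)
        angle = _wedge_free_angle(rng, hemifield)
        pop_cfg = PopulationConfig(
            n_subunits=cfg.population.n_subunits,
            size_intercept=a,
            size_slope=b,
            size_log_sd=cfg.population.size_log_sd,
            scatter_coeff=cfg.population.scatter_coeff,
            sf_size_constant=cfg.population.sf_size_constant,
        )
        pop = sample_population(ecc, angle, pop_cfg, rng, vertex_id=vid)
        overlaps = subunit_overlaps(pop, apertures)
        vertex_bold = {}
        for condition in ("high_adapted", "low_adapted"):
            sigma_truth = effective_sigma_oracle(
                pop, condition, cfg.adaptation, apertures.grid
            )
            pop.truth_sigma[condition] = sigma_truth
            neural = pop.gains(condition, cfg.adaptation) @ overlaps
            clean = (
                cfg.amplitude * np.convolve(neural, kernel)[: neural.shape[0]]
                + cfg.baseline
            )
            sig_sd = clean.std()
            if cfg.noise_sd is not None:
                nsd = cfg.noise_sd
            elif sig_sd > 0:
                nsd = noise_sd_for_reliability(
                    sig_sd, cfg.target_split_half_r, half
                )
            else:
                nsd = 1.0
            runs = clean[None, :] + rng.normal(0.0, nsd, (half, clean.shape[0]))
            vertex_bold[condition] = runs
        bold[vid] = vertex_bold
        populations.append(pop)
        truth_rows.append(
            {
                "vertex_id": vid,
                "roi": roi_name,
                "hemifield": hemifield,
                "ecc_deg": ecc,
                "angle_rad": angle,
                "truth_sigma_high": pop.truth_sigma["high_adapted"],
                "truth_sigma_low": pop.truth_sigma["low_adapted"],
            }
        )
    truth = pd.DataFrame(truth_rows)
    return FMRIDataset(
        truth=truth,
        bold=bold,
        populations=populations,
        run_labels=run_labels,
        tr=apertures.tr,
    )


@dataclass(frozen=True)
class ObserverModel:
    """2AFC observer: condition-dependent perceived-SF shift plus internal
    noise (both in log-SF units) and a symmetric lapse rate."""

    pse_shift: dict | None = None  # condition -> log-SF shift
    noise_sd: float = 0.15
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.lapse <= 0.1):
            raise ValueError("lapse must be in [0, 0.1]")

    def shift(self, condition: str) -> float:
        if self.pse_shift is None:
            return 0.0
        return float(self.pse_shift.get(condition, 0.0))


def simulate_observer_response(
    test_log_sf: float,
    ref_log_sf: float,
    condition: str,
    observer: ObserverModel,
    rng: np.random.Generator,
) -> str:
    """One 2AFC decision: 'test_higher' or 'ref_higher'.

    The reference is perceived at ``ref_log_sf + shift[condition]``; the
    decision variable adds Gaussian internal noise, and with probability
    ``lapse`` the choice is uniform at random.
    """
    if not (np.isfinite(test_log_sf) and np.isfinite(ref_log_sf)):
        raise ValueError("stimulus levels must be finite")
    if rng.random() < observer.lapse:
        return "test_higher" if rng.random() < 0.5 else "ref_higher"
    d = test_log_sf - (ref_log_sf + observer.shift(condition))
    d += rng.normal(0.0, observer.noise_sd)
    return "test_higher" if d > 0 else "ref_higher"
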