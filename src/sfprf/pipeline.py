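"""End-to-end orchestration: simulate → condition → fit → QC → statistics.

One seeded pipeline run generates apertures and a multi-participant
synthetic dataset, fits every vertex under both adapter conditions,
applies the reliability-based QC, computes the group statistics (medians,
Mood's tests with FDR, sliding eccentricity profiles, the ROI × SF
repeated-measures ANOVA where applicable) and the psychophysics arm, and
writes tables, figures and a machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import psychophysics as psy
from . import reliability as rel
from . import stats as st
from .hrf import HRFSpec, hrf_kernel
from .prf import DesignMatrices, GridPredictions, fit_vertex, make_search_grid
from .simulate import (
    AdaptationModel,
    FMRISimConfig,
    ObserverModel,
    PopulationConfig,
    simulate_fmri_dataset,
)
from .stimulus import ApertureSequence, FieldGrid, MaskGeometry, RunDesign, build_run_apertures

log = logging.getLogger("sfprf")

__all__ = [
    "PipelineConfig",
    "FitOptions",
    "StatsOptions",
    "PsychophysicsOptions",
    "derive_seed",
    "validate_config",
    "config_hash",
    "preprocess_and_fit",
    "run_pipeline",
]


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2³¹) from the root seed and stage name."""
    digest = hashlib.blake2s(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class FitOptions:
    """pRF-fitting options; ``coarsen`` subsamples the aperture grid by an
    integer factor for the forward model (speed), independent of the grid the
    data were generated on."""

    coarsen: int = 2
    n_ecc: int = 12
    max_ecc: float = 9.0
    n_angles: int = 24
    n_sigmas: int = 16
    sigma_min: float = 0.1
    sigma_max: float = 4.0
    xatol: float = 1e-4
    fatol: float = 1e-4
    maxiter: int = 500


@dataclass(frozen=True)
class StatsOptions:
    ecc_min: float = 0.0
    ecc_max: float = 8.0
    n_bins: int = 100
    bin_width: float = 1.0
    min_count: int = 10
    alpha: float = 0.05


@dataclass(frozen=True)
class PsychophysicsOptions:
    n_observers: int = 10
    n_sessions: int = 3
    shift_low: float = float(np.log(1.07))  # perceived SF +7% after low-SF adapt
    shift_high: float = float(np.log(0.87))  # −13% after high-SF adapt
    noise_sd: float = 0.15
    lapse: float = 0.02


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 1
    n_participants: int = 8
    grid: FieldGrid = FieldGrid()
    geometry: MaskGeometry = MaskGeometry()
    design: RunDesign = RunDesign()
    population: PopulationConfig = PopulationConfig()
    adaptation: AdaptationModel = AdaptationModel()
    hrf: HRFSpec = HRFSpec()
    n_vertices: int = 300
    n_runs: int = 6
    ecc_range: tuple = (0.5, 7.0)
    rois: tuple = (("V1", 0.25, 0.12),)
    amplitude: float = 1.0
    baseline: float = 100.0
    target_split_half_r: float = 0.7
    noise_sd: float | None = None
    fit: FitOptions = FitOptions()
    stats: StatsOptions = StatsOptions()
    psychophysics: PsychophysicsOptions = PsychophysicsOptions()
    run_psychophysics: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        self.fmri_config()  # validates run count, noise, ROIs

    def fmri_config(self) -> FMRISimConfig:
        return FMRISimConfig(
            n_vertices=self.n_vertices,
            n_runs=self.n_runs,
            ecc_range=tuple(self.ecc_range),
            rois=tuple(tuple(r) for r in self.rois),
            adaptation=self.adaptation,
            population=self.population,
            hrf=self.hrf,
            amplitude=self.amplitude,
            baseline=self.baseline,
            target_split_half_r=self.target_split_half_r,
            noise_sd=self.noise_sd,
        )


_SECTION_TYPES = {
    "grid": FieldGrid,
    "geometry": MaskGeometry,
    "design": RunDesign,
    "population": PopulationConfig,
    "adaptation": AdaptationModel,
    "hrf": HRFSpec,
    "fit": FitOptions,
    "stats": StatsOptions,
    "psychophysics": PsychophysicsOptions,
}


def _build_dataclass(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {path}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def build_config(data: dict) -> PipelineConfig:
    """Strict construction from a nested dict: unknown keys are rejected and
    every dataclass's own validation runs."""
    data = dict(data or {})
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            sub = data.pop(section)
            if not isinstance(sub, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            kwargs[section] = _build_dataclass(cls, sub, section)
    top = {f.name for f in dataclasses.fields(PipelineConfig)} - set(_SECTION_TYPES)
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return PipelineConfig(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; defaults fill missing sections."""
    with open(path) as f:
        data = yaml.safe_load(f)
    cfg = build_config(data or {})
    log.info("effective config: %s", cfg)
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_and_fit(
    dataset,
    apertures: ApertureSequence,
    hrf: HRFSpec = HRFSpec(),
    fit_options: FitOptions = FitOptions(),
    participant: int | None = None,
) -> pd.DataFrame:
    """Condition, average and fit every vertex × condition of one dataset.

    Runs are detrended/z-scored, the split-half noise ceiling computed, runs
    averaged, and the average fit with the coarse-to-fine pRF procedure on a
    (possibly coarsened) aperture grid.  Returns the fit table with
    reliability columns (split_half_r, ceiling, nr2) attached.
    """
    ap_fit = apertures.coarsen(fit_options.coarsen)
    kernel = hrf_kernel(hrf, tr=ap_fit.tr)
    design = DesignMatrices(ap_fit, kernel)
    grid = make_search_grid(
        fit_options.n_ecc,
        fit_options.max_ecc,
        fit_options.n_angles,
        fit_options.n_sigmas,
        fit_options.sigma_min,
        fit_options.sigma_max,
    )
    preds = GridPredictions(design, grid)
    truth = dataset.truth.set_index("vertex_id")
    rows = []
    for vid, conds in dataset.bold.items():
        for cond, runs in conds.items():
            try:
                conditioned = np.vstack([rel.detrend_zscore(r) for r in runs])
            except ValueError:
                rows.append(
                    {
                        "participant": participant,
                        "vertex_id": vid,
                        "condition": cond,
                        "flag": "failed:constant run",
                    }
                )
                continue
            ceiling = rel.noise_ceiling(conditioned)
            avg = rel.average_runs(conditioned)
            fit = fit_vertex(
                avg,
                design,
                preds,
                xatol=fit_options.xatol,
                fatol=fit_options.fatol,
                maxiter=fit_options.maxiter,
            )
            row = fit.as_row(vertex_id=vid, condition=cond)
            row["participant"] = participant
            row["split_half_r"] = ceiling.split_half_r
            row["ceiling"] = ceiling.ceiling
            row["nr2"] = rel.normalized_r2(fit.r2, ceiling.ceiling)
            if vid in truth.index:
                row["roi"] = truth.loc[vid, "roi"]
                row["truth_sigma"] = truth.loc[
                    vid,
                    "truth_sigma_high" if cond == "high_adapted" else "truth_sigma_low",
                ]
            rows.append(row)
    return pd.DataFrame(rows)


def _participant_profiles(kept: pd.DataFrame, opts: StatsOptions):
    profiles = []
    for _, grp in kept.groupby("participant"):
        hi = grp[grp["condition"] == "high_adapted"]
        lo = grp[grp["condition"] == "low_adapted"]
        if hi.empty or lo.empty:
            continue
        try:
            diffs = st.size_difference(hi, lo)
        except ValueError:
            continue
        profiles.append(
            st.sliding_bins(
                diffs["ecc_deg"].to_numpy(),
                diffs["diff_deg"].to_numpy(),
                n_bins=opts.n_bins,
                width=opts.bin_width,
                ecc_range=(opts.ecc_min, opts.ecc_max),
                min_count=opts.min_count,
            )
        )
    return profiles


def _plots(out: Path, medians: pd.DataFrame, profile: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rois = sorted(medians["roi"].unique())
    fig, axes = plt.subplots(1, len(rois), figsize=(3 * len(rois), 3), squeeze=False)
    for ax, roi in zip(axes[0], rois):
        sub = medians[medians["roi"] == roi].pivot(
            index="participant", columns="condition", values="median_sigma"
        )
        for _, row in sub.iterrows():
            ax.plot(
                [0, 1],
                [row.get("low_adapted"), row.get("high_adapted")],
                "o-",
                color="0.6",
                ms=4,
            )
        ax.plot(
            [0, 1],
            [sub["low_adapted"].mean(), sub["high_adapted"].mean()],
            "D-",
            color="k",
        )
        ax.set_xticks([0, 1], ["low", "high"])
        ax.set_title(roi)
        ax.set_ylabel("median pRF size (deg)")
    fig.tight_layout()
    fig.savefig(out / "fig_median_by_condition.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    v = profile.dropna(subset=["mean_diff"])
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(v["ecc_center"], v["mean_diff"], color="tab:purple")
    ax.fill_between(
        v["ecc_center"],
        v["mean_diff"] - v["sem"],
        v["mean_diff"] + v["sem"],
        alpha=0.3,
        color="tab:purple",
    )
    ax.set_xlabel("eccentricity (deg)")
    ax.set_ylabel("pRF size difference H−L (deg)")
    fig.tight_layout()
    fig.savefig(out / "fig_profile.png", dpi=120)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run the full simulate → fit → QC → stats flow; returns the summary.

    Writes fits.csv, qc.csv, summary.csv (medians), tests.csv, bins.csv,
    anova.csv (when ≥2 ROIs), behaviour tables, two figures and
    summary.json under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    apertures = build_run_apertures(cfg.design, cfg.geometry, cfg.grid)
    log.info("stage apertures: %d frames", apertures.n_frames)
    fmri_cfg = cfg.fmri_config()
    fit_frames = []
    for p in range(cfg.n_participants):
        ds = simulate_fmri_dataset(
            fmri_cfg, apertures, derive_seed(cfg.seed, f"fmri:{p}")
        )
        fits = preprocess_and_fit(
            ds, apertures, hrf=cfg.hrf, fit_options=cfg.fit, participant=p
        )
        fit_frames.append(fits)
        log.info("stage fit participant %d: %d rows", p, len(fits))
    fits = pd.concat(fit_frames, ignore_index=True)
    fits.to_csv(out / "fits.csv", index=False)

    qc = rel.filter_vertices(fits.dropna(subset=["sigma_deg"]))
    qc.to_csv(out / "qc.csv", index=False)
    kept = qc[qc["keep"]]
    log.info("stage qc: kept %d of %d fits", len(kept), len(qc))

    medians, tests = st.group_summary(kept, alpha=cfg.stats.alpha)
    medians.to_csv(out / "summary.csv", index=False)
    tests.to_csv(out / "tests.csv", index=False)

    profiles = _participant_profiles(kept, cfg.stats)
    profile = (
        st.group_profile(profiles)
        if profiles
        else pd.DataFrame(columns=["ecc_center", "mean_diff", "sem", "n_participants"])
    )
    profile.to_csv(out / "bins.csv", index=False)

    anova = None
    if len(cfg.rois) >= 2 and cfg.n_participants >= 2:
        cells = medians.rename(
            columns={"median_sigma": "sigma", "condition": "sf"}
        )
        cells["sf"] = cells["sf"].map(
            {"high_adapted": "high", "low_adapted": "low"}
        )
        try:
            anova = st.rm_anova_roi_sf(cells)
            anova.table.to_csv(out / "anova.csv", index=False)
        except (ValueError, KeyError) as err:
            log.warning("anova skipped: %s", err)

    summary: dict = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "n_participants": cfg.n_participants,
        "n_fits": int(len(qc)),
        "fraction_excluded": float(1.0 - len(kept) / max(len(qc), 1)),
    }
    wide = medians.pivot_table(
        index=["participant", "roi"], columns="condition", values="median_sigma"
    ).reset_index()
    roi_flags = {}
    for roi, grp in wide.groupby("roi"):
        roi_flags[roi] = {
            "median_sigma_high": float(grp["high_adapted"].mean()),
            "median_sigma_low": float(grp["low_adapted"].mean()),
            "sigma_high_gt_low": bool(
                grp["high_adapted"].mean() > grp["low_adapted"].mean()
            ),
            "n_participants_high_gt_low": int(
                (grp["high_adapted"] > grp["low_adapted"]).sum()
            ),
        }
    summary["rois"] = roi_flags
    summary["sigma_high_gt_low"] = bool(
        all(v["sigma_high_gt_low"] for v in roi_flags.values())
    )
    valid = profile.dropna(subset=["mean_diff"])
    summary["profile_bins_valid"] = int(len(valid))
    summary["profile_fraction_above_zero"] = (
        float((valid["mean_diff"] > 0).mean()) if len(valid) else None
    )
    has_truth = kept.dropna(subset=["truth_sigma"]) if "truth_sigma" in kept else kept.iloc[0:0]
    if len(has_truth):
        err = has_truth["sigma_deg"] - has_truth["truth_sigma"]
        summary["sigma_recovery_rmse"] = float(np.sqrt(np.mean(err**2)))
    if anova is not None:
        summary["anova"] = {
            row["effect"]: {"F": float(row["F"]), "p_gg": float(row["p_gg"])}
            for _, row in anova.table.iterrows()
        }

    if cfg.run_psychophysics:
        popt = cfg.psychophysics
        trial_frames = []
        for o in range(popt.n_observers):
            observer = ObserverModel(
                pse_shift={
                    "low_adapt": popt.shift_low,
                    "high_adapt": popt.shift_high,
                    "none": 0.0,
                },
                noise_sd=popt.noise_sd,
                lapse=popt.lapse,
            )
            rng = np.random.default_rng(derive_seed(cfg.seed, f"psy:{o}"))
            for s in range(popt.n_sessions):
                trial_frames.append(
                    psy.run_session(observer, rng, participant=o, session=s)
                )
        trials = pd.concat(trial_frames, ignore_index=True)
        trials.to_csv(out / "trials.csv", index=False)
        table, group = psy.analyze_behaviour(trials, task="sf")
        table.to_csv(out / "pse.csv", index=False)
        group.to_csv(out / "behaviour_tests.csv", index=False)
        summary["behaviour"] = {
            row["test"]: {
                "mean_percent": float(row["mean_percent"]),
                "t": float(row["t"]),
            }
            for _, row in group.iterrows()
        }
        log.info("stage psychophysics: %d trials", len(trials))

    try:
        _plots(out, medians, profile)
    except Exception as err:  # plotting must never sink the pipeline
        log.warning("plotting failed: %s", err)

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    return summary
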