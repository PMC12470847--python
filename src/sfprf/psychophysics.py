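"""Behavioural arm: adaptive staircases, psychometric fits, and aftereffects.

The SF-matching task: after adapting to a high (3.5 cpd) or low (0.5 cpd) SF
noise pattern in one hemifield, the observer judges which of two patches has
the higher SF — a mid-SF reference (~1.3 cpd, the adapters' geometric mean)
on the adapted side versus a variable test on the other side.  Two
interleaved 1-up-1-down staircases (starting 3.8 and 0.2 cpd, 30 trials
each) drive the test SF to the point of subjective equality (PSE).  Pooled
trials are fit with a cumulative Gaussian in log SF (a log-normal
psychometric function); the PSE is the half-proportion point, corrected for
response bias by subtracting the no-adaptation PSE, and expressed as a
percent change of perceived SF.

The contrast-control task reuses the same design with test *contrast* as the
staircase variable; because the reference sits at the top of the tested
range, PSEs there come from staircase reversals (drop the first three,
exclude ±2 MAD outliers, average the rest) rather than a psychometric fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator

from .simulate import ObserverModel, simulate_observer_response
from .stimulus import geometric_mean_sf

__all__ = [
    "SF_LEVELS",
    "CONTRAST_LEVELS",
    "Staircase",
    "StaircaseRejected",
    "TRIAL_COLUMNS",
    "run_block",
    "run_session",
    "PsychometricCurve",
    "PsychometricFit",
    "fit_psychometric",
    "bias_correct",
    "aftereffect_percent",
    "reversal_pse",
    "analyze_behaviour",
]

#: 30 test SFs, 0.2–3.8 cpd, evenly spaced (spacing ≈ 0.124 cpd, matching the
#: terminal staircase step).
SF_LEVELS = np.linspace(0.2, 3.8, 30)

#: 30 test contrasts, 0.01 upward in steps of 0.031, last level clamped to
#: the maximum contrast 1.0 (the printed endpoints and step disagree).
CONTRAST_LEVELS = np.concatenate([0.01 + 0.031 * np.arange(29), [1.0]])

#: Reference SF: geometric mean of the two adapter SFs (≈1.32 cpd).
REFERENCE_SF = geometric_mean_sf(0.5, 3.5)

TRIAL_COLUMNS = [
    "participant",
    "session",
    "task",
    "condition",
    "side",
    "block",
    "staircase_id",
    "trial",
    "level",
    "ref_level",
    "response",
    "reversal",
]


class StaircaseRejected(ValueError):
    """A staircase with too few usable reversals for a PSE estimate."""


@dataclass
class Staircase:
    """1-up-1-down staircase over a discrete level set.

    The level moves one step against each response; on a response reversal
    the step halves down to ``step_floor``.  Levels snap to the nearest
    member of ``levels`` (ties toward ``reference``) and clamp to the set's
    range.  Terminates after ``max_trials`` responses.
    """

    levels: np.ndarray
    start: float
    step: float = 0.5
    step_floor: float = 0.125
    reference: float = REFERENCE_SF
    max_trials: int = 30

    trial_count: int = field(default=0, init=False)
    last_direction: int | None = field(default=None, init=False)
    reversal_levels: list = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        self.levels = np.sort(np.asarray(self.levels, dtype=float))
        if self.step <= 0 or self.step_floor <= 0:
            raise ValueError("steps must be positive")
        self.level = self._snap(self.start)

    @property
    def terminated(self) -> bool:
        return self.trial_count >= self.max_trials

    def _snap(self, target: float) -> float:
        d = np.abs(self.levels - target)
        near = np.flatnonzero(d <= d.min() + 1e-12)
        if near.size > 1:  # tie: prefer the level closer to the reference
            near = near[np.argmin(np.abs(self.levels[near] - self.reference))]
            return float(self.levels[near])
        return float(self.levels[near[0]])

    def update(self, direction: str) -> bool:
        """Apply one response; ``direction`` is 'down' (move level down) or
        'up'.  Returns True if this response was a reversal (recorded at the
        level just presented)."""
        if self.terminated:
            raise RuntimeError("staircase already terminated")
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        d = -1 if direction == "down" else 1
        reversal = self.last_direction is not None and d != self.last_direction
        if reversal:
            self.reversal_levels.append(self.level)
            self.step = max(self.step / 2.0, self.step_floor)
        self.last_direction = d
        self.trial_count += 1
        self.level = self._snap(
            float(np.clip(self.level + d * self.step, self.levels[0], self.levels[-1]))
        )
        return reversal


def run_block(
    observer: ObserverModel,
    condition: str,
    side: str,
    rng: np.random.Generator,
    task: str = "sf",
    participant: int = 0,
    session: int = 0,
    block: int = 0,
) -> pd.DataFrame:
    """One block: two interleaved staircases (high/low start), 30 trials each.

    Which staircase runs on a given trial alternates randomly; once one
    terminates the other finishes alone.  Judgments come from the simulated
    observer in log-stimulus space; a 'test higher' response moves the test
    level down (1-up-1-down, converging on the 50% point).
    """
    if task == "sf":
        levels, starts = SF_LEVELS, (3.8, 0.2)
        step, floor, ref = 0.5, 0.125, REFERENCE_SF
    elif task == "contrast":
        levels, starts = CONTRAST_LEVELS, (1.0, 0.1)
        step, floor, ref = 0.124, 0.031, 1.0
    else:
        raise ValueError("task must be 'sf' or 'contrast'")
    stairs = [
        Staircase(levels, start=s, step=step, step_floor=floor, reference=ref)
        for s in starts
    ]
    rows = []
    trial = 0
    while any(not s.terminated for s in stairs):
        active = [i for i, s in enumerate(stairs) if not s.terminated]
        i = active[0] if len(active) == 1 else int(rng.integers(2))
        sc = stairs[i]
        level = sc.level
        choice = simulate_observer_response(
            math.log(level), math.log(ref), condition, observer, rng
        )
        reversal = sc.update("down" if choice == "test_higher" else "up")
        rows.append(
            {
                "participant": participant,
                "session": session,
                "task": task,
                "condition": condition,
                "side": side,
                "block": block,
                "staircase_id": i,
                "trial": trial,
                "level": level,
                "ref_level": ref,
                "response": choice,
                "reversal": reversal,
            }
        )
        trial += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_session(
    observer: ObserverModel,
    rng: np.random.Generator,
    task: str = "sf",
    participant: int = 0,
    session: int = 0,
) -> pd.DataFrame:
    """One session: six blocks (3 conditions × 2 sides), 60 trials each.

    The two no-adaptation blocks always come first (avoiding carry-over from
    lingering adaptation); the four adaptation blocks follow in random order.
    """
    first = [("none", "left"), ("none", "right")]
    rng.shuffle(first)
    rest = [
        (c, s) for c in ("low_adapt", "high_adapt") for s in ("left", "right")
    ]
    rng.shuffle(rest)
    frames = [
        run_block(
            observer, c, s, rng, task=task, participant=participant,
            session=session, block=b,
        )
        for b, (c, s) in enumerate(first + rest)
    ]
    return pd.concat(frames, ignore_index=True)


class PsychometricCurve(BaseEstimator):
    """Maximum-likelihood cumulative Gaussian in log stimulus space.

    P(test judged higher) = λ + (1 − 2λ)·Φ((x − pse)/s) with a single
    symmetric guess/lapse rate λ ∈ [0, lapse_max].  ``fit(X, y)`` takes log
    levels and binary responses (1 = test judged higher); fitted attributes
    are ``pse_``, ``slope_``, ``lapse_``, ``loglik_`` and ``pse_ci_`` (Wald
    95% interval).  The PSE is the half-proportion point of the fitted curve.
    """

    def __init__(self, lapse_max: float = 0.05):
        self.lapse_max = lapse_max

    @staticmethod
    def _prob(x, pse, s, lapse):
        return lapse + (1 - 2 * lapse) * sps.norm.cdf((x - pse) / s)

    def fit(self, X, y) -> "PsychometricCurve":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape or x.size == 0:
            raise ValueError("X and y must be nonempty and equal length")
        if np.unique(x).size < 2:
            raise ValueError("need at least two distinct stimulus levels")
        if y.min() == y.max():
            raise ValueError(
                "responses are all one way; data do not bracket the 50% point"
            )

        def nll(theta):
            pse, log_s, lapse = theta
            p = self._prob(x, pse, math.exp(log_s), lapse)
            p = np.clip(p, 1e-9, 1 - 1e-9)
            return -float(y @ np.log(p) + (1 - y) @ np.log1p(-p))

        # init: level weighted by response crossing, moderate slope
        order = np.argsort(x)
        p0 = np.array([float(np.interp(0.5, np.clip(
            np.cumsum(y[order]) / np.maximum(np.arange(x.size) + 1, 1), 1e-3, 1
        ), x[order])), math.log(0.2), 0.01])
        if not np.isfinite(p0[0]):
            p0[0] = float(np.median(x))
        res = optimize.minimize(
            nll,
            p0,
            method="L-BFGS-B",
            bounds=[
                (x.min() - 2.0, x.max() + 2.0),
                (math.log(1e-3), math.log(5.0)),
                (0.0, self.lapse_max),
            ],
        )
        self.pse_, log_s, self.lapse_ = res.x
        self.slope_ = math.exp(log_s)
        self.loglik_ = -float(res.fun)
        # Wald CI from a finite-difference second derivative in the PSE
        h = 1e-4
        d2 = (
            nll(res.x + [h, 0, 0]) - 2 * res.fun + nll(res.x - [h, 0, 0])
        ) / (h * h)
        se = 1.0 / math.sqrt(d2) if d2 > 0 else float("nan")
        self.pse_ci_ = (self.pse_ - 1.96 * se, self.pse_ + 1.96 * se)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "pse_"):
            raise AttributeError("PsychometricCurve is not fitted")
        return self._prob(np.asarray(X, dtype=float), self.pse_, self.slope_, self.lapse_)


@dataclass(frozen=True)
class PsychometricFit:
    pse: float  # log cpd
    slope: float
    lapse: float
    loglik: float
    pse_ci: tuple[float, float]


def fit_psychometric(trials: pd.DataFrame, lapse_max: float = 0.05) -> PsychometricFit:
    """Fit pooled trials of one condition; PSE in natural-log SF units."""
    x = np.log(trials["level"].to_numpy(dtype=float))
    y = (trials["response"] == "test_higher").to_numpy(dtype=float)
    curve = PsychometricCurve(lapse_max=lapse_max).fit(x, y)
    return PsychometricFit(
        pse=float(curve.pse_),
        slope=float(curve.slope_),
        lapse=float(curve.lapse_),
        loglik=float(curve.loglik_),
        pse_ci=curve.pse_ci_,
    )


def bias_correct(pse_adapt: float, pse_none: float) -> float:
    """Response-bias-corrected aftereffect: pse_adapt − pse_none (log units)."""
    if not (np.isfinite(pse_adapt) and np.isfinite(pse_none)):
        raise ValueError("PSEs must be finite")
    return float(pse_adapt - pse_none)


def aftereffect_percent(shift: float) -> float:
    """Perceived-SF change implied by a log-unit PSE shift: (e^shift − 1)·100."""
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    return (math.exp(shift) - 1.0) * 100.0


def reversal_pse(reversals, n_drop: int = 3, mad_factor: float = 2.0) -> float:
    """Reversal-based PSE: mean reversal level after burn-in and MAD pruning.

    ``reversals`` is the ordered list of reversal levels of one staircase (or
    a trial table with ``level``/``reversal`` columns).  The first ``n_drop``
    reversals are discarded; of the rest, values more than ``mad_factor``
    (unscaled) median absolute deviations from their median are excluded and
    the survivors averaged.  Staircases with ≤ ``n_drop`` reversals — or
    where pruning removes everything — raise :class:`StaircaseRejected`.
    """
    if isinstance(reversals, pd.DataFrame):
        reversals = reversals.loc[reversals["reversal"], "level"].to_numpy()
    levels = np.asarray(reversals, dtype=float)
    if levels.size <= n_drop:
        raise StaircaseRejected(
            f"only {levels.size} reversals (need more than {n_drop})"
        )
    rest = levels[n_drop:]
    med = float(np.median(rest))
    mad = float(np.median(np.abs(rest - med)))
    keep = rest[np.abs(rest - med) <= mad_factor * mad]
    if keep.size == 0:
        raise StaircaseRejected("all reversals excluded by the MAD rule")
    return float(keep.mean())


def _sf_participant_table(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for p, ptrials in trials.groupby("participant"):
        pses = {}
        for cond, ctrials in ptrials.groupby("condition"):
            pses[cond] = fit_psychometric(ctrials).pse
        ref_log = math.log(float(ptrials["ref_level"].iloc[0]))
        for cond in ("low_adapt", "high_adapt", "none"):
            if cond not in pses:
                continue
            raw_shift = pses[cond] - ref_log
            row = {
                "participant": p,
                "condition": cond,
                "pse_log": pses[cond],
                "raw_shift_log": raw_shift,
                "raw_percent": aftereffect_percent(raw_shift),
            }
            if cond != "none" and "none" in pses:
                shift = bias_correct(pses[cond], pses["none"])
                row["shift_log"] = shift
                row["percent"] = aftereffect_percent(shift)
            rows.append(row)
    return pd.DataFrame(rows)


def _contrast_participant_table(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for p, ptrials in trials.groupby("participant"):
        log_pse = {}
        for cond, ctrials in ptrials.groupby("condition"):
            vals = []
            for _, sc in ctrials.groupby(["session", "block", "staircase_id"]):
                try:
                    vals.append(math.log(reversal_pse(sc)))
                except StaircaseRejected:
                    continue
            if vals:
                log_pse[cond] = float(np.mean(vals))
        for cond in ("low_adapt", "high_adapt", "none"):
            if cond not in log_pse:
                continue
            row = {"participant": p, "condition": cond, "pse_log": log_pse[cond]}
            if cond != "none" and "none" in log_pse:
                row["shift_log"] = bias_correct(log_pse[cond], log_pse["none"])
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_behaviour(
    trials: pd.DataFrame, task: str = "sf"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level PSEs/shifts and group tests for one task.

    SF task: trials are pooled over sessions and sides per condition, fit
    with the log-normal psychometric function, bias-corrected against the
    no-adaptation PSE, and the bias-corrected log shifts of the two
    adaptation conditions enter one-sample t-tests (Bonferroni ×2); the
    no-adaptation raw shift is tested against zero uncorrected.

    Contrast task: PSEs come from staircase reversals per measurement,
    log-averaged per condition; the group test is a paired t-test of the
    bias-corrected shifts, high vs low adaptation.
    """
    if task == "sf":
        table = _sf_participant_table(trials)
        rows = []
        for cond in ("low_adapt", "high_adapt"):
            vals = table.loc[table["condition"] == cond, "shift_log"].dropna()
            if len(vals) < 2:
                continue
            t, praw = sps.ttest_1samp(vals, 0.0)
            rows.append(
                {
                    "test": f"{cond}_shift_vs_0",
                    "n": len(vals),
                    "mean_percent": float(
                        table.loc[table["condition"] == cond, "percent"].mean()
                    ),
                    "t": float(t),
                    "p_bonferroni": min(1.0, 2 * float(praw)),
                }
            )
        none_vals = table.loc[table["condition"] == "none", "raw_shift_log"].dropna()
        if len(none_vals) > 1:
            t, praw = sps.ttest_1samp(none_vals, 0.0)
            rows.append(
                {
                    "test": "none_raw_vs_0",
                    "n": len(none_vals),
                    "mean_percent": float(
                        table.loc[table["condition"] == "none", "raw_percent"].mean()
                    ),
                    "t": float(t),
                    "p_bonferroni": float(praw),
                }
            )
        return table, pd.DataFrame(rows)
    if task == "contrast":
        table = _contrast_participant_table(trials)
        wide = table.pivot(index="participant", columns="condition", values="shift_log")
        rows = []
        if {"high_adapt", "low_adapt"} <= set(wide.columns):
            paired = wide[["high_adapt", "low_adapt"]].dropna()
            if len(paired) > 1:
                t, p = sps.ttest_rel(paired["high_adapt"], paired["low_adapt"])
                rows.append(
                    {
                        "test": "high_vs_low_perceived_contrast",
                        "n": len(paired),
                        "t": float(t),
                        "p": float(p),
                    }
                )
        return table, pd.DataFrame(rows)
    raise ValueError("task must be 'sf' or 'contrast'")
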