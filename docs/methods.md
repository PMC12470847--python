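# Methods

`sfprf` implements, end to end and on synthetic data, the computational chain
used to ask whether spatial-frequency (SF) adaptation changes population
receptive field (pRF) sizes in early visual cortex: stimulus construction,
a generative model of adapted voxel responses, 2D-Gaussian pRF estimation,
reliability-based quality control, group statistics, and the psychophysical
staircase analysis of the SF aftereffect.

## Stimulus model

The mapping stimulus is represented as per-volume *binary* apertures on a
square grid of visual-field positions (default half-extent 7.5°, resolution
0.1°; x rightward, y upward). A run is 330 volumes at TR = 1 s: 25 baseline,
30 initial adaptation, eight 25-step bar sweeps with 25-volume blanks after
sweeps 4 and 8, and 25 closing baseline volumes; the 250 sweep/blank volumes
form the mapping sequence used for fitting. Bars are 1.15° wide with
half-overlapping steps (0.575°), travel span 13.8°, the first sweep
bottom-to-top and each next sweep rotated 45° clockwise. All bar frames are
clipped to the stimulated region: a 15°-diameter aperture minus a 0.7°
central occluder and two 20°-wide wedges over the vertical meridians (the
wedges keep each hemifield's adapter from stimulating the other). A sample
belongs to a region when its centre satisfies the inequality (half-open at
the outer radius). The on-screen alpha-gradient edges and per-volume top-up
adapters are deliberately *not* represented: the adapters stimulate the same
region in every volume, so their contribution carries no mapping information,
and the model is fit to the binary bar representation.

## Generative model of adaptation

Each simulated vertex pools `n_subunits` (default 8) neural subunits.
Subunit RF sizes are log-normal with median `a + b·ecc` (defaults a = 0.25°,
b = 0.12°/deg, a V1-like eccentricity scaling; configurable per simulated
ROI) and log-SD 0.4; centres scatter isotropically with SD 0.5 × the median
size. Preferred SF follows the scale-invariance rule `pref_sf = c/rf_size`
with c = 0.65 cpd·deg, chosen so a 0.5° subunit prefers the 1.3 cpd mapping
SF (the geometric mean of the 0.5 and 3.5 cpd adapters). Adaptation
multiplies each subunit's gain by `1 − A·exp(−d²/2w²)` with d the octave
distance from the adapter SF; defaults A = 0.5, w = 1 octave place the
mapping SF (~1.4 octaves from both adapters) inside the ≤2-octave transfer
range reported for SF adaptation. These functional forms and spreads are the
package's own quantitative reading of a qualitative mechanism; only the
adapter SFs, the run design and the exclusion rules are fixed by the
experimental design being emulated.

Each vertex's ground truth is an *oracle*: the least-squares best single 2D
Gaussian (amplitude profiled out) fit to the gain-weighted sum of
mass-normalised subunit Gaussians — mass-normalised because the response
model divides each subunit's stimulus overlap by its total mass, so the
aggregate profile a pRF fit "sees" weights subunits by gain, not by area.
Under the defaults the oracle σ is larger after high-SF than after low-SF
adaptation for essentially every mixed-size vertex, by roughly 5% — the
simulated counterpart of the empirical effect.

BOLD runs are `amplitude · (neural ⊛ HRF) + baseline + iid Gaussian noise`.
Runs alternate HL/LH adapter layouts (high-SF left / low-SF right, then
swapped), so a vertex's condition in a run is the adapter in its hemifield
and every vertex accrues `n_runs/2` runs per condition. Noise is calibrated
per vertex, via the closed-form split-half formula for iid noise, to a
target split-half reliability (default 0.7) at the default six runs; an
absolute noise SD can be set instead. Noise has no temporal autocorrelation
— a known simplification; the pipeline's statistics are correlation-based
and no empirical noise spectrum is modelled. Consequently, green recovery
tests establish internal consistency of the estimator and the direction and
robustness of the adaptation effect under realistic reliability, not
performance under structured physiological noise.

## pRF estimation

The forward model is the normalised overlap of an isotropic 2D Gaussian
(x0, y0, σ) with each binary aperture, convolved with a canonical
double-gamma HRF and restricted to the mapping volumes (convolution runs on
the full 330 volumes so spillover across blank boundaries is modelled). The
HRF is parametrised so each gamma lobe's *mode* equals its stated delay
(defaults 6 s peak, 16 s undershoot, dispersions 1, peak:undershoot 6),
peak-normalised.

Fitting maximises Pearson correlation: an exhaustive coarse grid (12 linear
eccentricities 0–9°, 24 polar angles, 16 log-spaced sigmas 0.1–4°;
zero-variance predictions get −∞; ties break to the first cell in grid
order) followed by Nelder-Mead from the best cell (xatol = fatol = 1e-4,
500 iterations max; if the simplex ends below its start the grid optimum is
returned with a flag). σ is unconstrained — degenerate outputs are caught by
the downstream filter. Amplitude and baseline then come from OLS of the
observed series on the prediction; the prediction is z-scored first, so beta
is in units of observed-series SD (for the z-scored inputs the pipeline
fits, a perfect fit has beta ≈ 1, keeping the 0.01–3 amplitude filter
meaningful). R² is the squared Pearson correlation.

Numerical choices: model evaluation uses float32 design matrices with the
HRF convolution of the vectorised frames precomputed once per design; the
batch pipeline evaluates the forward model on a factor-2 coarsened aperture
grid (0.2°) for speed. On noiseless single-Gaussian data the estimator
recovers parameters to well under 0.01° at the native grid; the coarsened
grid adds up to ~0.1° position and a few percent σ error, common to both
conditions and hence immaterial for the high-minus-low contrast it serves.

## Reliability and QC

Each run is linearly detrended (order fixed at 1) and z-scored, runs of a
condition averaged. Reliability is the Pearson correlation between odd- and
even-run means, Spearman-Brown corrected with the doubling factor k = 2
(each half is already an average; the general-k alternative is a switch).
That corrected reliability is used directly as the noise ceiling and as the
denominator of nR² = R²/ceiling (squaring the ceiling first is exposed as a
config switch). Negative split-half correlations clamp the ceiling to 0 —
an unreliable vertex cannot bound goodness of fit — which forces exclusion.
Vertices are dropped when σ ≤ 0, when the fit sits exactly at the origin,
when beta < 0.01 or > 3, or when nR² < 0.2; boundary values are kept, and
`reason` records the first violated rule.

## Group statistics

Per participant and ROI, raw pRF sizes of the two conditions are compared
with Mood's median test (pooled-median 2×2 table, Pearson χ², df 1, no
continuity correction; ties count as "not above"), with Benjamini-Hochberg
FDR across the participant × ROI family at q < 0.05. Participant-level
medians enter a two-way repeated-measures ANOVA (ROI × adapted SF) with
Greenhouse-Geisser correction for effects with more than one df. Per-vertex
size differences (high − low, on QC-passed vertices present in both
conditions; the between-condition mean eccentricity is used for binning)
are summarised by 100 sliding 1°-wide eccentricity bins over 0–8° (per-bin
median; bins with fewer than 10 vertices are dropped; the per-participant
bin medians are averaged with between-participant SEM). The proportional
change measure is the symmetric percent difference
(σH − σL)/((σH + σL)/2) — chosen for its antisymmetry and boundedness where
the exact published appendix formula is not available.

## Psychophysics

The SF task uses two interleaved 1-up-1-down staircases per block (starts
3.8 and 0.2 cpd; initial step 0.5 cpd halved at each response reversal down
to 0.125 ≈ 0.13 cpd; 30 trials each) over 30 evenly spaced test SFs
0.2–3.8 cpd (spacing ≈ 0.124, matching the terminal step; levels snap to
the set, ties toward the reference). A session is six blocks — two
no-adaptation blocks always first, then low/high × left/right shuffled.
The simulated observer adds a condition-dependent shift to the perceived
reference (defaults +ln 1.07 after low-SF, ln 0.87 after high-SF
adaptation), Gaussian internal noise (0.15 log units) and a 2% lapse rate.
Pooled trials per condition are fit by maximum likelihood with a cumulative
Gaussian in log SF and a single symmetric guess/lapse rate bounded at 0.05
(a deliberate simplification of Psignifit's prior machinery); the PSE is
the half-proportion point, bias-corrected by subtracting the no-adaptation
PSE, and reported as (e^shift − 1)·100 percent. Group inference: one-sample
t-tests on the bias-corrected log shifts, Bonferroni-corrected over the two
adaptation conditions.

The contrast-control task swaps the staircase variable to test contrast
(30 levels, 0.01 in steps of 0.031 with the last level clamped to the
maximum 1.0, because the printed endpoints and step are mutually
inconsistent; staircase starts 0.1 and 1.0, initial step 0.124 halved to a
floor of one level spacing — a choice, since no step rule is printed for
this task). Because the reference sits at the top of the testable range,
PSEs come from staircase reversals: drop the first three, exclude values
beyond ±2 unscaled median absolute deviations from the median, average the
survivors; staircases with three or fewer reversals are rejected.

## Pipeline and reproducibility

`run_pipeline` (CLI: `sfprf reproduce`) chains apertures → per-participant
simulation → conditioning/fit → QC → statistics → psychophysics and writes
tables, figures and `summary.json` (per-ROI medians, direction flags,
profile coverage, σ-recovery RMSE against the oracle truth, behaviour
recoveries, config hash). One root seed drives everything; per-stage seeds
derive from a stable hash of (seed, stage name), so equal configurations
are bit-identical. YAML configs are schema-checked with unknown keys
rejected.

## Known limitations

- iid Gaussian noise; no temporal autocorrelation, motion or physiological
  structure.
- No orientation tuning, contrast nonlinearity, surround suppression or
  compressive spatial summation; the fitted model is the plain 2D Gaussian.
- The generator's functional forms (log-normal sizes, Gaussian octave-space
  suppression) are one concrete realisation of a qualitative hypothesis.
- Psychometric fitting simplifies Psignifit's Bayesian treatment to plain
  maximum likelihood with a bounded symmetric lapse.
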