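"""Synthetic-data generator: adaptation gains, populations, BOLD, observer."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st_
from scipy import stats

from sfprf.simulate import (
    ADAPTER_SF,
    AdaptationModel,
    FMRISimConfig,
    NeuralPopulation,
    NeuralSubunit,
    ObserverModel,
    PopulationConfig,
    adaptation_gain,
    bold_from_neural,
    effective_prf_oracle,
    effective_sigma_oracle,
    neural_timecourse,
    noise_sd_for_reliability,
    sample_population,
    simulate_fmri_dataset,
    simulate_observer_response,
)
from sfprf.stimulus import build_run_apertures, FieldGrid


class TestAdaptationGain:
    def test_at_adapter_sf(self):
        m = AdaptationModel(suppression=0.4)
        assert adaptation_gain(3.5, 3.5, m) == pytest.approx(0.6)

    def test_no_suppression(self):
        m = AdaptationModel(suppression=0.0)
        for sf in (0.2, 1.3, 3.5):
            assert adaptation_gain(sf, 0.5, m) == 1.0

    def test_far_from_adapter(self):
        m = AdaptationModel(suppression=0.5, bandwidth_octaves=1.0)
        # 4 octaves away: 1 − A·e^−8
        assert adaptation_gain(8.0, 0.5, m) == pytest.approx(
            1 - 0.5 * math.exp(-8), abs=1e-12
        )

    @given(d=st_.floats(0.01, 4), f=st_.floats(0.2, 4))
    def test_symmetric_in_octave_distance(self, d, f):
        m = AdaptationModel(suppression=0.5, bandwidth_octaves=0.8)
        up = adaptation_gain(f * 2**d, f, m)
        down = adaptation_gain(f * 2**-d, f, m)
        assert up == pytest.approx(down, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adaptation_gain(-1, 0.5, AdaptationModel())
        with pytest.raises(ValueError):
            AdaptationModel(suppression=1.0)


class TestSamplePopulation:
    def test_degenerate_single_subunit(self, rng):
        cfg = PopulationConfig(n_subunits=1, scatter_coeff=0.0, size_log_sd=0.0)
        pop = sample_population(3.0, 0.5, cfg, rng)
        (u,) = pop.subunits
        assert (u.x, u.y) == pytest.approx(pop.nominal_xy)
        assert u.rf_size == pytest.approx(0.25 + 0.12 * 3.0)

    def test_scale_invariance_rule_exact(self, rng):
        cfg = PopulationConfig(n_subunits=50)
        pop = sample_population(2.0, 0.0, cfg, rng)
        for u in pop.subunits:
            assert u.pref_sf * u.rf_size == pytest.approx(0.65, rel=1e-12)

    def test_size_median_matches_generator(self, rng):
        # large-sample check against the generating median a + b·ecc
        cfg = PopulationConfig(n_subunits=100_000)
        pop = sample_population(4.0, 0.0, cfg, rng)
        sizes = [u.rf_size for u in pop.subunits]
        assert np.median(sizes) == pytest.approx(0.25 + 0.12 * 4.0, rel=0.02)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_subunits=0)


class TestEffectiveSigmaOracle:
    def test_single_subunit_recovered_exactly(self):
        pop = NeuralPopulation(
            0, 3.0, 0.0, [NeuralSubunit(3.0, 0.0, 0.6, 1.0)]
        )
        m = AdaptationModel(suppression=0.0)
        x0, y0, s = effective_prf_oracle(pop, "high_adapted", m)
        assert (x0, y0) == pytest.approx((3.0, 0.0), abs=1e-3)
        assert s == pytest.approx(0.6, abs=1e-3)

    def test_identical_subunits_collapse(self):
        subs = [NeuralSubunit(1.0, 1.0, 0.5, 1.3)] * 3
        pop = NeuralPopulation(0, math.sqrt(2), math.pi / 4, subs)
        s = effective_sigma_oracle(pop, "low_adapted", AdaptationModel(0.0))
        assert s == pytest.approx(0.5, abs=1e-3)

    def test_high_adapter_silences_small_rfs(self):
        # small subunit prefers high SF: high-SF adaptation weights the
        # aggregate toward the large subunit → bigger effective sigma
        subs = [
            NeuralSubunit(2.0, 0.0, 0.2, 0.65 / 0.2),
            NeuralSubunit(2.0, 0.0, 1.0, 0.65 / 1.0),
        ]
        pop = NeuralPopulation(0, 2.0, 0.0, subs)
        m = AdaptationModel(suppression=0.8, bandwidth_octaves=1.0)
        hi = effective_sigma_oracle(pop, "high_adapted", m)
        lo = effective_sigma_oracle(pop, "low_adapted", m)
        assert hi > lo

    def test_adapter_invariance_without_suppression(self, rng):
        pop = sample_population(3.0, 0.3, PopulationConfig(), rng)
        m = AdaptationModel(suppression=0.0)
        hi = effective_sigma_oracle(pop, "high_adapted", m)
        lo = effective_sigma_oracle(pop, "low_adapted", m)
        assert hi == pytest.approx(lo, rel=1e-9)


class TestNeuralTimecourse:
    def test_zero_and_full_frames(self, rng):
        from sfprf.stimulus import ApertureSequence

        grid = FieldGrid(4.0, 0.1)
        frames = np.stack(
            [np.zeros(grid.shape, np.uint8), np.ones(grid.shape, np.uint8)]
        )
        ap = ApertureSequence(grid=grid, frames=frames, annotations=["blank"] * 2)
        pop = sample_population(1.0, 0.2, PopulationConfig(n_subunits=4), rng)
        m = AdaptationModel()
        r = neural_timecourse(pop, "high_adapted", ap, m)
        gains = pop.gains("high_adapted", m)
        assert r[0] == 0.0
        assert r[1] == pytest.approx(gains.sum(), rel=1e-6)


class TestBoldFromNeural:
    def test_impulse_identity(self):
        series = np.sin(np.linspace(0, 6, 50))
        impulse = np.array([1.0])
        y = bold_from_neural(series, impulse)
        assert np.allclose(y, series)

    def test_zero_series_is_baseline_plus_noise(self, rng):
        y = bold_from_neural(np.zeros(2000), np.ones(5), baseline=7.0,
                             noise_sd=0.5, rng=rng)
        assert y.mean() == pytest.approx(7.0, abs=0.05)
        assert y.std() == pytest.approx(0.5, rel=0.1)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            bold_from_neural(np.zeros(5), np.ones(2), noise_sd=-1)


class TestNoiseCalibration:
    def test_round_trip_reliability(self):
        # the returned noise SD plugged back into the split-half formula
        # reproduces the requested reliability
        for k, r in [(3, 0.7), (5, 0.5), (2, 0.9)]:
            u = noise_sd_for_reliability(1.3, r, k) ** 2
            v = 1.3**2
            n1, n2 = (k + 1) // 2, k // 2
            pred = v / math.sqrt((v + u / n1) * (v + u / n2))
            assert pred == pytest.approx(r, rel=1e-9)


@pytest.fixture(scope="module")
def small_apertures(apertures):
    return apertures


class TestSimulateDataset:
    def test_structure_and_determinism(self, small_apertures):
        cfg = FMRISimConfig(n_vertices=4, n_runs=4)
        a = simulate_fmri_dataset(cfg, small_apertures, 5)
        b = simulate_fmri_dataset(cfg, small_apertures, 5)
        assert a.truth.equals(b.truth)
        for v in range(4):
            for cond in ("high_adapted", "low_adapted"):
                assert a.bold[v][cond].shape == (2, 330)
                assert np.array_equal(a.bold[v][cond], b.bold[v][cond])

    def test_no_adaptation_equal_truth(self, small_apertures):
        cfg = FMRISimConfig(
            n_vertices=4, n_runs=4, adaptation=AdaptationModel(suppression=0.0)
        )
        ds = simulate_fmri_dataset(cfg, small_apertures, 2)
        assert np.allclose(ds.truth.truth_sigma_high, ds.truth.truth_sigma_low)

    def test_default_effect_direction(self, small_apertures):
        cfg = FMRISimConfig(n_vertices=12, n_runs=4)
        ds = simulate_fmri_dataset(cfg, small_apertures, 9)
        assert (
            ds.truth.truth_sigma_high.median() > ds.truth.truth_sigma_low.median()
        )

    def test_odd_run_count_rejected(self):
        with pytest.raises(ValueError):
            FMRISimConfig(n_runs=5)

    def test_run_labels_alternate(self, small_apertures):
        cfg = FMRISimConfig(n_vertices=1, n_runs=6)
        ds = simulate_fmri_dataset(cfg, small_apertures, 0)
        assert ds.run_labels == ["HL", "LH", "HL", "LH", "HL", "LH"]


class TestObserver:
    def test_deterministic_limit(self):
        obs = ObserverModel(noise_sd=1e-9, lapse=0.0)
        rng = np.random.default_rng(0)
        c = simulate_observer_response(
            math.log(1.4), math.log(1.3), "none", obs, rng
        )
        assert c == "test_higher"

    def test_half_point_at_shifted_reference(self, rng):
        shift = math.log(1.07)
        obs = ObserverModel(pse_shift={"low_adapt": shift}, noise_sd=0.2, lapse=0.0)
        n = 4000
        hits = sum(
            simulate_observer_response(
                math.log(1.3) + shift, math.log(1.3), "low_adapt", obs, rng
            )
            == "test_higher"
            for _ in range(n)
        )
        assert hits / n == pytest.approx(0.5, abs=0.025)

    def test_choice_proportions_match_gaussian(self, rng):
        # Monte-Carlo choice rates vs the closed-form cumulative Gaussian
        obs = ObserverModel(noise_sd=0.25, lapse=0.0)
        ref = math.log(1.3)
        for delta in (-0.3, 0.1, 0.4):
            n = 4000
            hits = sum(
                simulate_observer_response(ref + delta, ref, "none", obs, rng)
                == "test_higher"
                for _ in range(n)
            )
            assert hits / n == pytest.approx(
                stats.norm.cdf(delta / 0.25), abs=0.03
            )

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            simulate_observer_response(
                math.nan, 0.0, "none", ObserverModel(), rng
            )
        with pytest.raises(ValueError):
            ObserverModel(noise_sd=0.0)
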