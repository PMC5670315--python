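"""Simulator: determinism, observation models, occupancy, end-to-end shape."""

from __future__ import annotations

import math
from datetime import datetime

import numpy as np

from hragree.epoching import pair_streams
from hragree.mvpa_detection import build_contingency, diagnostic_metrics
from hragree.stream_io import Participant
from hragree.synthetic_cohort import (
    ActivityState,
    CohortScenario,
    DeviceErrorModel,
    StateParams,
    TruthTrajectory,
    observe_reference,
    observe_test,
    simulate_cohort,
    simulate_truth,
)

T0 = datetime(2024, 3, 4, 10, 0, 0)


def small_scenario(**overrides) -> CohortScenario:
    defaults = dict(
        n_participants=3,
        session_hours=(1.0, 1.5),
        followup_days=3,
        rng_seed=7,
    )
    defaults.update(overrides)
    return CohortScenario(**defaults)


def _assert_truth_equal(a, b):
    """Field-wise equality treating NaN minute means (nonwear) as equal."""
    assert (a.beta0, a.beta1, a.rest_hr, a.session_start) == (
        b.beta0,
        b.beta1,
        b.rest_hr,
        b.session_start,
    )
    np.testing.assert_array_equal(
        np.array(a.session_true_minute_means), np.array(b.session_true_minute_means)
    )
    assert a.session_true_zone_minutes == b.session_true_zone_minutes
    assert a.followup_worn_days == b.followup_worn_days


class TestDeterminism:
    def test_same_seed_reproduces_cohort_exactly(self):
        a = simulate_cohort(small_scenario())
        b = simulate_cohort(small_scenario())
        assert a.participants == b.participants
        for pid in a.validation_test:
            assert a.validation_test[pid].samples == b.validation_test[pid].samples
            assert a.validation_reference[pid].samples == b.validation_reference[pid].samples
            assert a.followup_test[pid].samples == b.followup_test[pid].samples
        for pid in a.truth:
            _assert_truth_equal(a.truth[pid], b.truth[pid])

    def test_adding_a_participant_never_perturbs_others(self):
        a = simulate_cohort(small_scenario(n_participants=2))
        b = simulate_cohort(small_scenario(n_participants=3))
        for pid in a.validation_test:
            assert a.validation_test[pid].samples == b.validation_test[pid].samples
            _assert_truth_equal(a.truth[pid], b.truth[pid])

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_scenario(rng_seed=1))
        b = simulate_cohort(small_scenario(rng_seed=2))
        assert any(
            a.validation_test[pid].samples != b.validation_test[pid].samples
            for pid in a.validation_test
        )


class TestTruthProcess:
    def test_single_state_trajectory_stays_in_band(self):
        scenario = CohortScenario(
            states={ActivityState.REST: StateParams((0.30, 0.38), 25.0)},
            transitions={ActivityState.REST: {ActivityState.REST: 1.0}},
            rng_seed=0,
        )
        p = Participant("P01", 25.0)
        rng = np.random.default_rng(0)
        traj = simulate_truth(p, scenario, 120, rng, T0)
        hrmax = 195.0
        lo, hi = 0.30 * hrmax, 0.38 * hrmax
        # allow the mean-reverting noise (~2 bpm SD) some slack
        assert np.nanmin(traj.hr) > lo - 10
        assert np.nanmax(traj.hr) < hi + 10
        assert set(traj.states) == {ActivityState.REST}

    def test_fixed_seed_trajectory_reproducible(self):
        p = Participant("P01", 25.0)
        scenario = CohortScenario(rng_seed=0)
        a = simulate_truth(p, scenario, 60, np.random.default_rng(5), T0)
        b = simulate_truth(p, scenario, 60, np.random.default_rng(5), T0)
        np.testing.assert_array_equal(a.hr, b.hr)
        assert a.states == b.states

    def test_occupancy_matches_stationary_distribution(self):
        """Empirical state occupancy over long runs agrees with the
        semi-Markov stationary distribution (visit frequencies from the
        embedded chain, weighted by mean dwell)."""
        scenario = CohortScenario(rng_seed=0)
        order = [
            ActivityState.REST,
            ActivityState.LIGHT,
            ActivityState.MVPA_BOUT,
            ActivityState.NONWEAR,
        ]
        P = np.array(
            [[scenario.transitions[a].get(b, 0.0) for b in order] for a in order]
        )
        # stationary visit distribution of the embedded chain
        eigvals, eigvecs = np.linalg.eig(P.T)
        pi = np.real(eigvecs[:, np.argmin(np.abs(eigvals - 1.0))])
        pi = pi / pi.sum()
        dwell = np.array([scenario.states[s].mean_dwell_min for s in order])
        occupancy = pi * dwell / (pi * dwell).sum()

        p = Participant("P01", 25.0)
        reps = []
        for rep in range(6):
            traj = simulate_truth(p, scenario, 2000, np.random.default_rng(100 + rep), T0)
            counts = np.array([sum(s is st for s in traj.states) for st in order], dtype=float)
            reps.append(counts / counts.sum())
        reps = np.array(reps)
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / math.sqrt(len(reps))
        for j, state in enumerate(order):
            assert abs(mean[j] - occupancy[j]) <= 3 * se[j] + 0.01, (
                f"{state}: empirical {mean[j]:.3f} vs stationary {occupancy[j]:.3f}"
            )


def _constant_truth(hr_bpm: float, minutes: int) -> TruthTrajectory:
    n = minutes * 60
    return TruthTrajectory(
        start=T0,
        hr=np.full(n, hr_bpm),
        states=(ActivityState.REST,) * n,
    )


def _nonwear_truth(minutes: int) -> TruthTrajectory:
    n = minutes * 60
    return TruthTrajectory(start=T0, hr=np.full(n, np.nan), states=(ActivityState.NONWEAR,) * n)


NOISELESS = DeviceErrorModel(
    bias_intercept_mean=0.0,
    bias_intercept_sd=0.0,
    bias_slope_mean=0.0,
    bias_slope_sd=0.0,
    noise_sd_test=0.0,
    noise_sd_reference=0.0,
    test_dropout_prob=0.0,
    reference_dropout_prob=0.0,
)


class TestObservation:
    def test_noiseless_reference_equals_rounded_truth(self, participant):
        truth = _constant_truth(80.4, 5)
        stream = observe_reference(truth, participant, NOISELESS, np.random.default_rng(0))
        assert len(stream) == 30  # every 10 s
        assert set(s.hr_bpm for s in stream.samples) == {80}

    def test_nonwear_reference_is_all_zero(self, participant):
        stream = observe_reference(
            _nonwear_truth(3), participant, NOISELESS, np.random.default_rng(0)
        )
        assert all(s.hr_bpm == 0 for s in stream.samples)

    def test_reference_dropout_rate_matches_binomial(self, participant):
        em = DeviceErrorModel(reference_dropout_prob=0.1, noise_sd_reference=0.0)
        truth = _constant_truth(80.0, 1700)  # 10200 ticks
        stream = observe_reference(truth, participant, em, np.random.default_rng(3))
        zero_frac = sum(s.hr_bpm == 0 for s in stream.samples) / len(stream)
        se = math.sqrt(0.1 * 0.9 / len(stream))
        assert abs(zero_frac - 0.1) <= 3 * se

    def test_unbiased_noiseless_test_equals_minute_truth_mean(self, participant):
        truth = _constant_truth(112.0, 4)
        stream, true_means = observe_test(
            truth, participant, (0.0, 0.0), 65.0, NOISELESS, np.random.default_rng(0)
        )
        assert [s.hr_bpm for s in stream.samples] == [112] * 4
        np.testing.assert_allclose(true_means, 112.0)

    def test_intensity_dependent_bias_formula(self, participant):
        # rest 65, truth 145 (80 above rest): bias = -4 - 0.15*80 = -16
        truth = _constant_truth(145.0, 2)
        stream, _ = observe_test(
            truth, participant, (-4.0, -0.15), 65.0, NOISELESS, np.random.default_rng(0)
        )
        assert [s.hr_bpm for s in stream.samples] == [129, 129]

    def test_mostly_nonwear_minute_emits_zero(self, participant):
        hr = np.full(120, np.nan)
        hr[:20] = 100.0  # 20 worn seconds < half the first minute
        hr[60:] = 100.0  # second minute fully worn
        truth = TruthTrajectory(start=T0, hr=hr, states=(ActivityState.REST,) * 120)
        stream, true_means = observe_test(
            truth, participant, (0.0, 0.0), 65.0, NOISELESS, np.random.default_rng(0)
        )
        assert stream.samples[0].hr_bpm == 0
        assert stream.samples[1].hr_bpm == 100
        assert math.isnan(true_means[0])


class TestCohortShape:
    def test_zero_hazard_means_every_day_worn(self):
        cohort = simulate_cohort(small_scenario(daily_wear_hazard=0.0, followup_days=5))
        for t in cohort.truth.values():
            assert t.followup_worn_days == (1, 2, 3, 4, 5)

    def test_ground_truth_zone_minutes_cover_session(self):
        cohort = simulate_cohort(small_scenario())
        for pid, t in cohort.truth.items():
            n_minutes = len(t.session_true_minute_means)
            assert sum(t.session_true_zone_minutes.values()) == n_minutes
            assert len(cohort.validation_test[pid]) == n_minutes

    def test_sensitivity_below_one_and_decreasing_in_bias_slope(self):
        """The steeper the negative intensity slope, the more MVPA minutes
        the test device pushes below the cutoff."""
        sens = []
        for slope in (0.0, -0.15, -0.35):
            em = DeviceErrorModel(
                bias_intercept_mean=-4.0,
                bias_intercept_sd=0.0,
                bias_slope_mean=slope,
                bias_slope_sd=0.0,
            )
            scenario = CohortScenario(
                n_participants=6,
                session_hours=(3.0, 4.0),
                followup_days=0,
                error_model=em,
                rng_seed=11,
            )
            cohort = simulate_cohort(scenario)
            pairs = []
            for pid in cohort.validation_test:
                pairs += pair_streams(
                    cohort.validation_test[pid], cohort.validation_reference[pid]
                )
            m = diagnostic_metrics(build_contingency(pairs))
            sens.append(m.sensitivity.value)
        assert sens[1] < 1.0
        assert sens[0] >= sens[1] >= sens[2]
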