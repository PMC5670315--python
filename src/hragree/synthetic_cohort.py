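"""Synthetic free-living cohort generator.

No raw device data ship with this package, so every pipeline stage is
exercised against simulated cohorts that reproduce the statistical
structure the analysis assumes:

* a per-second "true" heart-rate trajectory driven by a semi-Markov
  activity process (rest / light activity / MVPA bouts / nonwear) with
  exponential dwell times, a per-bout target intensity expressed as a
  fraction of the participant's age-predicted maximal heart rate, a
  60-s-scale lag when the target changes (heart rate does not jump at
  activity transitions), and mean-reverting short-term variability;
* a chest-strap-style reference that reads the truth every 10 s with
  small noise and occasional dropout;
* a wrist-tracker-style test device that reports once per minute with a
  participant-specific systematic error: a random intercept (around
  −4 bpm) plus a random negative slope in heart rate above rest (around
  −0.15 bpm/bpm), so the underestimate grows with intensity — roughly
  −4 bpm at rest and −16 bpm deep in the MVPA zone;
* a month of follow-up in which only the test device is worn and
  day-level compliance decays geometrically.

Everything is driven by one integer seed through per-participant,
per-device spawned RNG streams: a fixed seed reproduces the cohort
bit-for-bit, and adding a participant never perturbs the others' data.
Ground truth (per-participant error coefficients, per-minute true means,
true zone minutes) is retained so recovery tests can compare estimates
against what was simulated.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from .hr_zones import DEFAULT_SCHEME, Zone, ZoneScheme, classify_zone, max_heart_rate
from .stream_io import (
    DeviceRole,
    HeartRateSample,
    Participant,
    SensorStream,
    write_participants,
    write_stream,
)

__all__ = [
    "ActivityState",
    "StateParams",
    "DeviceErrorModel",
    "CohortScenario",
    "TruthTrajectory",
    "ParticipantTruth",
    "CohortData",
    "simulate_truth",
    "observe_reference",
    "observe_test",
    "simulate_cohort",
]

HR_FLOOR_BPM = 25  # observed readings never fall below this after noise


class ActivityState(enum.Enum):
    NONWEAR = "nonwear"
    REST = "rest"
    LIGHT = "light"
    MVPA_BOUT = "mvpa_bout"


@dataclass(frozen=True)
class StateParams:
    """Target relative-intensity band and mean dwell time for one state.

    ``intensity_range`` is a (lo, hi) fraction of the participant's
    age-predicted maximal heart rate; None for nonwear (no heart rate
    emitted). Dwell times are exponential with the given mean.
    """

    intensity_range: tuple[float, float] | None
    mean_dwell_min: float


#: Default activity mix. Rest sits just above a typical resting heart
#: rate, light activity stays below the 50% MVPA threshold, and MVPA
#: bouts target 65-85% of maximal so the intensity-dependent device error
#: is fully expressed. Dwell means put roughly 7% of worn time in MVPA.
DEFAULT_STATES: Mapping[ActivityState, StateParams] = {
    ActivityState.REST: StateParams((0.28, 0.36), 25.0),
    ActivityState.LIGHT: StateParams((0.34, 0.44), 5.0),
    ActivityState.MVPA_BOUT: StateParams((0.65, 0.85), 5.0),
    ActivityState.NONWEAR: StateParams(None, 4.0),
}

DEFAULT_TRANSITIONS: Mapping[ActivityState, Mapping[ActivityState, float]] = {
    ActivityState.REST: {
        ActivityState.LIGHT: 0.60,
        ActivityState.MVPA_BOUT: 0.15,
        ActivityState.NONWEAR: 0.25,
    },
    ActivityState.LIGHT: {
        ActivityState.REST: 0.55,
        ActivityState.MVPA_BOUT: 0.35,
        ActivityState.NONWEAR: 0.10,
    },
    ActivityState.MVPA_BOUT: {
        ActivityState.REST: 0.45,
        ActivityState.LIGHT: 0.45,
        ActivityState.NONWEAR: 0.10,
    },
    ActivityState.NONWEAR: {
        ActivityState.REST: 0.70,
        ActivityState.LIGHT: 0.30,
    },
}


@dataclass(frozen=True)
class DeviceErrorModel:
    """Additive error structure of the two devices.

    The test device's error for a minute with true mean ``m`` is
    ``beta0_i + beta1_i * max(0, m - rest_hr_i)`` plus white noise, where
    (beta0_i, beta1_i) are participant-level normal draws. The reference
    adds only small white noise. Dropout probabilities act per reading
    (per minute for the test device, per 10-s tick for the reference).
    """

    bias_intercept_mean: float = -4.0
    bias_intercept_sd: float = 1.2
    bias_slope_mean: float = -0.15
    bias_slope_sd: float = 0.05
    noise_sd_test: float = 3.0
    noise_sd_reference: float = 1.5
    test_dropout_prob: float = 0.03
    reference_dropout_prob: float = 0.02

    def __post_init__(self) -> None:
        for name in ("bias_intercept_sd", "bias_slope_sd", "noise_sd_test", "noise_sd_reference"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("test_dropout_prob", "reference_dropout_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class CohortScenario:
    """Everything that defines one simulated study.

    Defaults describe a 10-person adult cohort (ages ~N(25, 4) truncated
    to 18-65), one 3-6 h paired validation session per participant, and
    30 days of test-device-only follow-up whose day-level wear
    probability decays geometrically with a 1%/day hazard. A worn
    follow-up day covers ~1050 (SD 150) contiguous minutes — most of the
    waking day — so nearly all worn days clear the 600-min valid-day
    rule, but the occasional short-wear day does not.
    """

    n_participants: int = 10
    age_mean: float = 25.4
    age_sd: float = 3.7
    age_bounds: tuple[float, float] = (18.0, 65.0)
    rest_hr_mean: float = 65.0
    rest_hr_sd: float = 6.0
    rest_hr_bounds: tuple[float, float] = (50.0, 85.0)
    session_hours: tuple[float, float] = (3.0, 6.0)
    followup_days: int = 30
    daily_wear_hazard: float = 0.01
    followup_wear_minutes_mean: float = 1050.0
    followup_wear_minutes_sd: float = 150.0
    states: Mapping[ActivityState, StateParams] = field(
        default_factory=lambda: dict(DEFAULT_STATES)
    )
    transitions: Mapping[ActivityState, Mapping[ActivityState, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITIONS.items()}
    )
    error_model: DeviceErrorModel = field(default_factory=DeviceErrorModel)
    zone_scheme: ZoneScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    start_date: date = date(2024, 3, 4)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.daily_wear_hazard <= 1.0:
            raise ValueError("daily_wear_hazard must be a probability")
        for origin, probs in self.transitions.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities from {origin} sum to {total}, not 1")


# --- truth process ----------------------------------------------------------

#: Exponential lag toward a new activity target: time constant such that
#: ~95% of a step is absorbed within 60 s.
_LAG_TAU_S = 20.0
#: Mean-reverting (AR(1)) short-term heart-rate variability.
_OU_THETA = 0.05  # per-second reversion rate
_OU_STATIONARY_SD = 2.0  # bpm


@dataclass(frozen=True)
class TruthTrajectory:
    """Per-second ground truth for one contiguous simulated window."""

    start: datetime  # minute-aligned
    hr: np.ndarray  # float per second; NaN while nonwear
    states: tuple[ActivityState, ...]  # per second

    @property
    def duration_s(self) -> int:
        return len(self.hr)


def _draw_bouts(
    scenario: CohortScenario, duration_s: int, rng: np.random.Generator
) -> list[tuple[ActivityState, int]]:
    """Semi-Markov bout sequence covering ``duration_s`` seconds."""
    bouts: list[tuple[ActivityState, int]] = []
    state = ActivityState.REST
    remaining = duration_s
    while remaining > 0:
        dwell = max(30, int(round(rng.exponential(scenario.states[state].mean_dwell_min * 60.0))))
        dwell = min(dwell, remaining)
        bouts.append((state, dwell))
        remaining -= dwell
        nxt = scenario.transitions[state]
        labels = list(nxt)
        state = labels[rng.choice(len(labels), p=[nxt[s] for s in labels])]
    return bouts


def _smooth_segment(targets: np.ndarray) -> np.ndarray:
    """Causal exponential lag toward the piecewise-constant target."""
    alpha = 1.0 - math.exp(-1.0 / _LAG_TAU_S)
    zi = np.array([(1.0 - alpha) * targets[0]])
    smoothed, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], targets, zi=zi)
    return smoothed


def _ou_segment(n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with ~2 bpm marginal SD."""
    phi = 1.0 - _OU_THETA
    sigma = _OU_STATIONARY_SD * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, sigma, size=n)
    x0 = rng.normal(0.0, _OU_STATIONARY_SD)
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def simulate_truth(
    participant: Participant,
    scenario: CohortScenario,
    duration_min: int,
    rng: np.random.Generator,
    start: datetime,
) -> TruthTrajectory:
    """Simulate one contiguous window of per-second true heart rate.

    The activity process draws bouts with exponential dwell; each bout
    targets a uniform draw from its state's intensity band times the
    participant's maximal heart rate. The realised trajectory lags the
    target (exponential, ~60 s to absorb a step) and carries
    mean-reverting variability. Nonwear seconds are NaN.
    """
    if duration_min < 1:
        raise ValueError("duration_min must be >= 1")
    if start.second or start.microsecond:
        raise ValueError("trajectory start must be minute-aligned")
    n = duration_min * 60
    hrmax = max_heart_rate(participant.age_years, scenario.zone_scheme)

    bouts = _draw_bouts(scenario, n, rng)
    target = np.empty(n)
    states: list[ActivityState] = []
    pos = 0
    for state, dwell in bouts:
        band = scenario.states[state].intensity_range
        if band is None:
            target[pos : pos + dwell] = np.nan
        else:
            target[pos : pos + dwell] = rng.uniform(band[0], band[1]) * hrmax
        states.extend([state] * dwell)
        pos += dwell

    hr = np.full(n, np.nan)
    wear = ~np.isnan(target)
    # process wear runs independently: heart rate restarts at the target
    # after a nonwear gap (no memory across removals)
    if wear.any():
        edges = np.flatnonzero(np.diff(wear.astype(int)) != 0) + 1
        bounds = np.concatenate([[0], edges, [n]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if not wear[lo]:
                continue
            seg = _smooth_segment(target[lo:hi]) + _ou_segment(hi - lo, rng)
            hr[lo:hi] = np.maximum(seg, 30.0)
    return TruthTrajectory(start=start, hr=hr, states=tuple(states))


# --- device observation -----------------------------------------------------


def observe_reference(
    truth: TruthTrajectory,
    participant: Participant,
    error_model: DeviceErrorModel,
    rng: np.random.Generator,
) -> SensorStream:
    """Chest-strap-style observation: every 10 s, truth + small noise.

    Readings are rounded to integer bpm and floored at 25; nonwear
    seconds and dropped ticks emit 0 (the no-reading sentinel).
    """
    idx = np.arange(0, truth.duration_s, 10)
    vals = truth.hr[idx]
    noise = rng.normal(0.0, error_model.noise_sd_reference, size=len(idx))
    dropped = rng.random(len(idx)) < error_model.reference_dropout_prob
    samples = []
    for t_off, v, nz, dr in zip(idx, vals, noise, dropped):
        if np.isnan(v) or dr:
            hr = 0
        else:
            hr = max(HR_FLOOR_BPM, int(round(v + nz)))
        samples.append(HeartRateSample(truth.start + timedelta(seconds=int(t_off)), hr))
    return SensorStream(participant, DeviceRole.REFERENCE, tuple(samples))


def observe_test(
    truth: TruthTrajectory,
    participant: Participant,
    effects: tuple[float, float],
    rest_hr: float,
    error_model: DeviceErrorModel,
    rng: np.random.Generator,
) -> tuple[SensorStream, np.ndarray]:
    """Wrist-tracker-style observation: one biased reading per minute.

    A minute's reading is the mean of the true heart rate over its worn
    seconds plus ``beta0 + beta1 * max(0, mean - rest_hr)`` plus noise,
    rounded and floored at 25. Minutes that are mostly nonwear (< 30 worn
    seconds) or hit by dropout emit 0. Returns the stream together with
    the per-minute true means (NaN for nonwear minutes) for
    ground-truth-aware tests.
    """
    beta0, beta1 = effects
    n_min = truth.duration_s // 60
    sec = truth.hr[: n_min * 60].reshape(n_min, 60)
    worn = (~np.isnan(sec)).sum(axis=1)
    sums = np.nansum(sec, axis=1)
    true_mean = np.where(worn >= 30, sums / np.maximum(worn, 1), np.nan)

    noise = rng.normal(0.0, error_model.noise_sd_test, size=n_min)
    dropped = rng.random(n_min) < error_model.test_dropout_prob

    samples = []
    for i in range(n_min):
        if np.isnan(true_mean[i]) or dropped[i]:
            hr = 0
        else:
            m = true_mean[i]
            biased = m + beta0 + beta1 * max(0.0, m - rest_hr) + noise[i]
            hr = max(HR_FLOOR_BPM, int(round(biased)))
        samples.append(HeartRateSample(truth.start + timedelta(minutes=i), hr))
    return SensorStream(participant, DeviceRole.TEST, tuple(samples)), true_mean


# --- cohort assembly --------------------------------------------------------


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground truth retained for one participant."""

    beta0: float
    beta1: float
    rest_hr: float
    session_start: datetime
    session_true_minute_means: tuple[float, ...]  # NaN encoded as None in JSON
    session_true_zone_minutes: Mapping[str, int]  # low / mvpa / nonwear counts
    followup_worn_days: tuple[int, ...]  # 1-based day indices actually worn


@dataclass(frozen=True)
class CohortData:
    """One simulated study: streams plus the generating truth."""

    scenario: CohortScenario
    participants: tuple[Participant, ...]
    validation_test: Mapping[str, SensorStream]
    validation_reference: Mapping[str, SensorStream]
    followup_test: Mapping[str, SensorStream]
    truth: Mapping[str, ParticipantTruth]

    def write(self, out_dir: str | Path) -> None:
        """Write the cohort as stream-dialect CSVs plus a truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_participants(list(self.participants), out / "participants.csv")
        for pid in sorted(self.validation_test):
            write_stream(self.validation_test[pid], out / f"validation_test_{pid}.csv")
            write_stream(self.validation_reference[pid], out / f"validation_reference_{pid}.csv")
            write_stream(self.followup_test[pid], out / f"followup_test_{pid}.csv")
        payload = {
            pid: {
                "beta0": t.beta0,
                "beta1": t.beta1,
                "rest_hr": t.rest_hr,
                "session_start": t.session_start.isoformat(),
                "session_true_minute_means": [
                    None if math.isnan(v) else v for v in t.session_true_minute_means
                ],
                "session_true_zone_minutes": dict(t.session_true_zone_minutes),
                "followup_worn_days": list(t.followup_worn_days),
            }
            for pid, t in sorted(self.truth.items())
        }
        (out / "ground_truth.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _participant_label(i: int) -> str:
    label = ""
    n = i
    while True:
        label = chr(ord("A") + n % 26) + label
        n = n // 26 - 1
        if n < 0:
            return label


def simulate_cohort(scenario: CohortScenario) -> CohortData:
    """Simulate the full study: paired validation session plus follow-up.

    Each participant gets an independent spawned RNG stream keyed by the
    scenario seed, so the cohort is bit-reproducible and grows without
    disturbing existing participants' data.
    """
    root = np.random.SeedSequence(scenario.rng_seed)
    participant_seeds = root.spawn(scenario.n_participants)

    participants: list[Participant] = []
    validation_test: dict[str, SensorStream] = {}
    validation_reference: dict[str, SensorStream] = {}
    followup_test: dict[str, SensorStream] = {}
    truth: dict[str, ParticipantTruth] = {}

    for i, seed in enumerate(participant_seeds):
        # independent sub-streams: traits, session truth, each device,
        # then one per follow-up day
        subs = seed.spawn(4 + scenario.followup_days)
        rng_traits = np.random.default_rng(subs[0])
        rng_truth = np.random.default_rng(subs[1])
        rng_ref = np.random.default_rng(subs[2])
        rng_test = np.random.default_rng(subs[3])

        pid = f"P{i + 1:02d}"
        age = _truncated_normal(
            rng_traits, scenario.age_mean, scenario.age_sd, *scenario.age_bounds
        )
        participant = Participant(pid, round(age, 1), label=_participant_label(i))
        participants.append(participant)

        em = scenario.error_model
        beta0 = float(rng_traits.normal(em.bias_intercept_mean, em.bias_intercept_sd))
        beta1 = float(rng_traits.normal(em.bias_slope_mean, em.bias_slope_sd))
        rest_hr = _truncated_normal(
            rng_traits, scenario.rest_hr_mean, scenario.rest_hr_sd, *scenario.rest_hr_bounds
        )

        # validation session: both devices worn concurrently on day 0
        dur_min = int(round(rng_traits.uniform(*scenario.session_hours) * 60.0))
        start_minute = int(rng_traits.integers(8 * 60, 16 * 60))
        session_start = datetime.combine(scenario.start_date, datetime.min.time()) + timedelta(
            minutes=start_minute
        )
        session = simulate_truth(participant, scenario, dur_min, rng_truth, session_start)
        validation_reference[pid] = observe_reference(session, participant, em, rng_ref)
        test_stream, true_means = observe_test(
            session, participant, (beta0, beta1), rest_hr, em, rng_test
        )
        validation_test[pid] = test_stream

        zone_minutes = {"low": 0, "mvpa": 0, "nonwear": 0}
        for m in true_means:
            if math.isnan(m):
                zone_minutes["nonwear"] += 1
            else:
                z = classify_zone(m, participant.age_years, scenario.zone_scheme)
                zone_minutes["low" if z is Zone.LOW else "mvpa"] += 1

        # follow-up: test device only, geometric compliance decay
        followup_samples: list[HeartRateSample] = []
        worn_days: list[int] = []
        for day in range(1, scenario.followup_days + 1):
            rng_day = np.random.default_rng(subs[3 + day])
            wear_prob = (1.0 - scenario.daily_wear_hazard) ** (day - 1)
            if rng_day.random() >= wear_prob:
                continue
            worn_days.append(day)
            wear_min = int(
                round(
                    _truncated_normal(
                        rng_day,
                        scenario.followup_wear_minutes_mean,
                        scenario.followup_wear_minutes_sd,
                        120.0,
                        1439.0,
                    )
                )
            )
            day_start_min = int(rng_day.integers(0, 1440 - wear_min))
            day_start = datetime.combine(
                scenario.start_date + timedelta(days=day), datetime.min.time()
            ) + timedelta(minutes=day_start_min)
            day_truth = simulate_truth(participant, scenario, wear_min, rng_day, day_start)
            day_stream, _ = observe_test(
                day_truth, participant, (beta0, beta1), rest_hr, em, rng_day
            )
            followup_samples.extend(day_stream.samples)
        followup_test[pid] = SensorStream(participant, DeviceRole.TEST, tuple(followup_samples))

        truth[pid] = ParticipantTruth(
            beta0=beta0,
            beta1=beta1,
            rest_hr=rest_hr,
            session_start=session_start,
            session_true_minute_means=tuple(float(v) for v in true_means),
            session_true_zone_minutes=zone_minutes,
            followup_worn_days=tuple(worn_days),
        )

    return CohortData(
        scenario=scenario,
        participants=tuple(participants),
        validation_test=validation_test,
        validation_reference=validation_reference,
        followup_test=followup_test,
        truth=truth,
    )
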