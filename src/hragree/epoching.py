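"""Clock-minute epoching, device pairing, and wear-day summaries.

The unit of analysis is the wall-clock minute: a half-open window
``[t, t+60s)`` with ``t`` aligned to a minute boundary. A 60-s test sample
is assigned to the minute containing its timestamp (floored, never split);
10-s reference samples falling inside a minute are aggregated. Zero
readings are nonwear sentinels and never contribute to an aggregate: the
reference epoch value is the mean of the *nonzero* samples in the minute,
and an epoch with no nonzero sample has value 0.

"Common wear" — the inclusion criterion for all paired agreement
analyses — is a minute in which both devices produced a nonzero epoch
value; all other minutes are excluded outright, never imputed.

Wear-day summaries follow the free-living convention: any minute with a
nonzero epoch value is a worn minute, a calendar day (local midnight to
midnight) with at least 600 worn minutes is a valid day, and each of the
1440 minutes of a day is either no-valid-reading, low, or MVPA.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Sequence

import pandas as pd

from .errors import PairingError
from .hr_zones import DEFAULT_SCHEME, Zone, ZoneScheme, classify_zone
from .stream_io import Participant, SensorStream

__all__ = [
    "Epoch",
    "PairedEpoch",
    "WearDaySummary",
    "VALID_DAY_MIN_EPOCHS",
    "MINUTES_PER_DAY",
    "minute_epochs",
    "pair_streams",
    "daily_wear_summaries",
    "pairs_to_frame",
    "summaries_to_frame",
]

MINUTES_PER_DAY = 1440
#: Minimum worn minutes for a calendar day to count as a valid wear day.
VALID_DAY_MIN_EPOCHS = 600


def floor_minute(ts: datetime) -> datetime:
    return ts.replace(second=0, microsecond=0)


@dataclass(frozen=True)
class Epoch:
    """One clock minute of one device.

    ``value_bpm`` is 0 exactly when no nonzero sample fell in the minute
    (``n_source_samples == 0``). ``range_width_bpm`` is max minus min of
    the contributing samples, 0 when one or none contributed.
    """

    start: datetime
    value_bpm: float
    n_source_samples: int
    range_width_bpm: float

    def __post_init__(self) -> None:
        if self.start.second or self.start.microsecond:
            raise ValueError(f"epoch start {self.start} is not minute-aligned")
        if (self.value_bpm == 0) != (self.n_source_samples == 0):
            raise ValueError(
                "value_bpm must be 0 exactly when no samples contributed "
                f"(value={self.value_bpm}, n={self.n_source_samples})"
            )


@dataclass(frozen=True)
class PairedEpoch:
    """A common-wear minute: both devices read nonzero."""

    participant: Participant
    start: datetime
    test_bpm: float
    reference_mean_bpm: float
    reference_range_width_bpm: float

    def __post_init__(self) -> None:
        if self.test_bpm <= 0 or self.reference_mean_bpm <= 0:
            raise ValueError("paired epochs require nonzero values on both devices")

    @property
    def difference_bpm(self) -> float:
        """Test minus reference; negative = the tracker underestimates."""
        return self.test_bpm - self.reference_mean_bpm


@dataclass(frozen=True)
class WearDaySummary:
    """Zone/wear accounting for one participant calendar day.

    The 1440 minutes of the day split exactly into no-valid-reading, low
    and MVPA counts; worn minutes are low + MVPA, and the day is valid
    when at least ``VALID_DAY_MIN_EPOCHS`` minutes were worn.
    """

    participant: Participant
    calendar_date: date
    n_noread: int
    n_low: int
    n_mvpa: int
    valid_day_min_epochs: int = VALID_DAY_MIN_EPOCHS

    def __post_init__(self) -> None:
        if self.n_noread + self.n_low + self.n_mvpa != MINUTES_PER_DAY:
            raise ValueError(
                f"zone counts must sum to {MINUTES_PER_DAY}: "
                f"{self.n_noread}+{self.n_low}+{self.n_mvpa}"
            )
        if min(self.n_noread, self.n_low, self.n_mvpa) < 0:
            raise ValueError("zone counts must be non-negative")

    @property
    def worn_epochs(self) -> int:
        return self.n_low + self.n_mvpa

    @property
    def is_valid_day(self) -> bool:
        return self.worn_epochs >= self.valid_day_min_epochs


def minute_epochs(stream: SensorStream, min_source_samples: int = 1) -> list[Epoch]:
    """Collapse a stream onto clock minutes.

    Produces one :class:`Epoch` per minute from the floor of the first
    timestamp through the floor of the last, inclusive — gaps included,
    as zero-valued epochs. Zero samples never contribute; a minute whose
    nonzero-sample count falls below ``min_source_samples`` is reported
    as no-reading (value 0, n 0). The default of 1 accepts any nonzero
    sample; set 6 to require a complete minute of 10-s reference data.
    """
    if not stream.samples:
        return []
    if min_source_samples < 1:
        raise ValueError("min_source_samples must be >= 1")

    per_minute: dict[datetime, list[int]] = {}
    for s in stream.samples:
        if s.hr_bpm > 0:
            per_minute.setdefault(floor_minute(s.timestamp), []).append(s.hr_bpm)

    first = floor_minute(stream.samples[0].timestamp)
    last = floor_minute(stream.samples[-1].timestamp)
    out: list[Epoch] = []
    t = first
    while t <= last:
        vals = per_minute.get(t, [])
        if len(vals) >= min_source_samples:
            out.append(
                Epoch(
                    start=t,
                    value_bpm=sum(vals) / len(vals),
                    n_source_samples=len(vals),
                    range_width_bpm=float(max(vals) - min(vals)) if len(vals) > 1 else 0.0,
                )
            )
        else:
            out.append(Epoch(start=t, value_bpm=0.0, n_source_samples=0, range_width_bpm=0.0))
        t += timedelta(minutes=1)
    return out


def pair_streams(
    test: SensorStream,
    reference: SensorStream,
    min_reference_samples: int = 1,
) -> list[PairedEpoch]:
    """Pair the test and reference streams on common-wear minutes.

    Returns exactly the minutes where both per-minute epoch values are
    nonzero, sorted by start time. Minutes worn on only one device (or
    neither) are dropped, not imputed. ``min_reference_samples`` is the
    minimum number of nonzero 10-s samples required for a reference
    minute to count (default 1; 6 demands the full complement).
    """
    if test.participant.participant_id != reference.participant.participant_id:
        raise PairingError(
            "cannot pair streams from different participants: "
            f"{test.participant.participant_id!r} vs "
            f"{reference.participant.participant_id!r}"
        )
    ref_by_start = {
        e.start: e
        for e in minute_epochs(reference, min_source_samples=min_reference_samples)
        if e.n_source_samples > 0
    }
    pairs: list[PairedEpoch] = []
    for e in minute_epochs(test):
        if e.n_source_samples == 0:
            continue
        ref = ref_by_start.get(e.start)
        if ref is None:
            continue
        pairs.append(
            PairedEpoch(
                participant=test.participant,
                start=e.start,
                test_bpm=e.value_bpm,
                reference_mean_bpm=ref.value_bpm,
                reference_range_width_bpm=ref.range_width_bpm,
            )
        )
    return pairs


def daily_wear_summaries(
    stream: SensorStream,
    zone_scheme: ZoneScheme = DEFAULT_SCHEME,
    valid_day_min_epochs: int = VALID_DAY_MIN_EPOCHS,
) -> list[WearDaySummary]:
    """Per-calendar-day wear and zone accounting for one (test) stream.

    Every date touched by the stream gets one summary covering all 1440
    minutes of that day; minutes outside the stream's span, gaps, and
    zero readings all count as no-valid-reading. Zone labels come from
    the per-minute epoch value and the participant's age.
    """
    epochs = minute_epochs(stream)
    if not epochs:
        return []
    age = stream.participant.age_years

    by_date: dict[date, dict[Zone, int]] = {}
    for e in epochs:
        counts = by_date.setdefault(e.start.date(), {Zone.LOW: 0, Zone.MVPA: 0})
        if e.n_source_samples > 0:
            counts[classify_zone(e.value_bpm, age, zone_scheme)] += 1
    # Dates merely spanned (fully silent) still get an all-noread summary.
    d = epochs[0].start.date()
    last = epochs[-1].start.date()
    while d <= last:
        by_date.setdefault(d, {Zone.LOW: 0, Zone.MVPA: 0})
        d += timedelta(days=1)

    out = []
    for day in sorted(by_date):
        counts = by_date[day]
        n_low, n_mvpa = counts[Zone.LOW], counts[Zone.MVPA]
        out.append(
            WearDaySummary(
                participant=stream.participant,
                calendar_date=day,
                n_noread=MINUTES_PER_DAY - n_low - n_mvpa,
                n_low=n_low,
                n_mvpa=n_mvpa,
                valid_day_min_epochs=valid_day_min_epochs,
            )
        )
    return out


def pairs_to_frame(pairs: Sequence[PairedEpoch]) -> pd.DataFrame:
    """Tidy frame of paired epochs (one row per common-wear minute)."""
    return pd.DataFrame(
        {
            "participant_id": [p.participant.participant_id for p in pairs],
            "start": [p.start for p in pairs],
            "test_bpm": [p.test_bpm for p in pairs],
            "reference_mean_bpm": [p.reference_mean_bpm for p in pairs],
            "reference_range_width_bpm": [p.reference_range_width_bpm for p in pairs],
            "difference_bpm": [p.difference_bpm for p in pairs],
        }
    )


def summaries_to_frame(summaries: Sequence[WearDaySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [s.participant.participant_id for s in summaries],
            "date": [s.calendar_date.isoformat() for s in summaries],
            "worn_epochs": [s.worn_epochs for s in summaries],
            "is_valid_day": [s.is_valid_day for s in summaries],
            "n_noread": [s.n_noread for s in summaries],
            "n_low": [s.n_low for s in summaries],
            "n_mvpa": [s.n_mvpa for s in summaries],
        }
    )
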