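"""MVPA-detection diagnostics and free-living wear summaries.

The detection question: treating the chest-strap reference as truth, how
often does the wrist tracker put a common-wear minute in the right
intensity zone? Each paired minute is classified twice — once from the
reference mean, once from the test value, both against the same
participant's age — and cross-tabulated into a 2×2 table with MVPA as the
positive class. Sensitivity, specificity, PPV and NPV are kept as exact
integer ratios; rounding happens only at display time.

The free-living side aggregates wear-day summaries over a follow-up
period: valid days only, zone-minute counts with their percentages, and
average daily MVPA minutes, plus a day-by-day adherence curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .epoching import MINUTES_PER_DAY, PairedEpoch, WearDaySummary
from .errors import DegenerateDataError, HrAgreeError
from .hr_zones import DEFAULT_SCHEME, Zone, ZoneScheme, classify_zone

__all__ = [
    "ContingencyTable",
    "RatioMetric",
    "DiagnosticMetrics",
    "FreeLivingSummary",
    "build_contingency",
    "diagnostic_metrics",
    "freeliving_summary",
    "adherence_curve",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ContingencyTable:
    """Reference zone × test zone counts of common-wear minutes.

    With MVPA as the positive class and the reference as truth:
    TP = ref_mvpa_test_mvpa, FN = ref_mvpa_test_low,
    FP = ref_low_test_mvpa, TN = ref_low_test_low.
    """

    ref_low_test_low: int
    ref_low_test_mvpa: int
    ref_mvpa_test_low: int
    ref_mvpa_test_mvpa: int

    def __post_init__(self) -> None:
        for name in (
            "ref_low_test_low",
            "ref_low_test_mvpa",
            "ref_mvpa_test_low",
            "ref_mvpa_test_mvpa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.ref_low_test_low
            + self.ref_low_test_mvpa
            + self.ref_mvpa_test_low
            + self.ref_mvpa_test_mvpa
        )

    @property
    def ref_low_total(self) -> int:
        return self.ref_low_test_low + self.ref_low_test_mvpa

    @property
    def ref_mvpa_total(self) -> int:
        return self.ref_mvpa_test_low + self.ref_mvpa_test_mvpa

    @property
    def test_low_total(self) -> int:
        return self.ref_low_test_low + self.ref_mvpa_test_low

    @property
    def test_mvpa_total(self) -> int:
        return self.ref_low_test_mvpa + self.ref_mvpa_test_mvpa

    # epidemiological aliases
    @property
    def tp(self) -> int:
        return self.ref_mvpa_test_mvpa

    @property
    def fn(self) -> int:
        return self.ref_mvpa_test_low

    @property
    def fp(self) -> int:
        return self.ref_low_test_mvpa

    @property
    def tn(self) -> int:
        return self.ref_low_test_low


@dataclass(frozen=True)
class RatioMetric:
    """An exact numerator/denominator pair with float and percent views."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    def percent(self, ndigits: int = 1) -> float:
        return round(100.0 * self.value, ndigits)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV with retained counts.

    A metric whose denominator is zero is undefined and reported as
    None rather than 0 or NaN.
    """

    sensitivity: RatioMetric | None
    specificity: RatioMetric | None
    ppv: RatioMetric | None
    npv: RatioMetric | None


def build_contingency(
    pairs: Sequence[PairedEpoch], scheme: ZoneScheme = DEFAULT_SCHEME
) -> ContingencyTable:
    """Cross-tabulate each paired minute's reference zone vs test zone."""
    if not pairs:
        raise HrAgreeError("build_contingency requires at least one paired epoch")
    cells = {
        (Zone.LOW, Zone.LOW): 0,
        (Zone.LOW, Zone.MVPA): 0,
        (Zone.MVPA, Zone.LOW): 0,
        (Zone.MVPA, Zone.MVPA): 0,
    }
    for p in pairs:
        age = p.participant.age_years
        ref_zone = classify_zone(p.reference_mean_bpm, age, scheme)
        test_zone = classify_zone(p.test_bpm, age, scheme)
        cells[(ref_zone, test_zone)] += 1
    return ContingencyTable(
        ref_low_test_low=cells[(Zone.LOW, Zone.LOW)],
        ref_low_test_mvpa=cells[(Zone.LOW, Zone.MVPA)],
        ref_mvpa_test_low=cells[(Zone.MVPA, Zone.LOW)],
        ref_mvpa_test_mvpa=cells[(Zone.MVPA, Zone.MVPA)],
    )


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Exact detection metrics from a 2×2 table (MVPA positive)."""
    if table.total == 0:
        raise DegenerateDataError("all-zero contingency table")

    def ratio(num: int, den: int) -> RatioMetric | None:
        return RatioMetric(num, den) if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.tn + table.fp),
        ppv=ratio(table.tp, table.tp + table.fp),
        npv=ratio(table.tn, table.tn + table.fn),
    )


@dataclass(frozen=True)
class FreeLivingSummary:
    """Zone-minute accounting over one participant's (or the pooled) valid days."""

    participant_id: str  # "overall" for the pooled row
    valid_days: int
    n_noread: int
    n_low: int
    n_mvpa: int

    def __post_init__(self) -> None:
        if self.n_noread + self.n_low + self.n_mvpa != self.total_epochs:
            raise ValueError(
                "zone counts must sum to valid_days * 1440: "
                f"{self.n_noread}+{self.n_low}+{self.n_mvpa} != {self.total_epochs}"
            )

    @property
    def total_epochs(self) -> int:
        return self.valid_days * MINUTES_PER_DAY

    @property
    def pct_noread(self) -> float:
        return 100.0 * self.n_noread / self.total_epochs if self.total_epochs else 0.0

    @property
    def pct_low(self) -> float:
        return 100.0 * self.n_low / self.total_epochs if self.total_epochs else 0.0

    @property
    def pct_mvpa(self) -> float:
        return 100.0 * self.n_mvpa / self.total_epochs if self.total_epochs else 0.0

    @property
    def avg_daily_mvpa_min(self) -> float:
        return self.n_mvpa / self.valid_days if self.valid_days else 0.0

    @property
    def avg_daily_mvpa_min_display(self) -> int:
        return round_half_away(self.avg_daily_mvpa_min)


def freeliving_summary(
    day_summaries: Sequence[WearDaySummary],
) -> tuple[list[FreeLivingSummary], FreeLivingSummary]:
    """Per-participant and pooled free-living summaries over *valid* days.

    Only valid days (>= the wear threshold) contribute; participants with
    zero valid days appear as explicit zero rows. Returns the
    per-participant rows (sorted by id) and the pooled "overall" row.
    """
    per: dict[str, list[WearDaySummary]] = {}
    for s in day_summaries:
        per.setdefault(s.participant.participant_id, []).append(s)

    rows: list[FreeLivingSummary] = []
    for pid in sorted(per):
        valid = [s for s in per[pid] if s.is_valid_day]
        rows.append(
            FreeLivingSummary(
                participant_id=pid,
                valid_days=len(valid),
                n_noread=sum(s.n_noread for s in valid),
                n_low=sum(s.n_low for s in valid),
                n_mvpa=sum(s.n_mvpa for s in valid),
            )
        )
    overall = FreeLivingSummary(
        participant_id="overall",
        valid_days=sum(r.valid_days for r in rows),
        n_noread=sum(r.n_noread for r in rows),
        n_low=sum(r.n_low for r in rows),
        n_mvpa=sum(r.n_mvpa for r in rows),
    )
    return rows, overall


def adherence_curve(day_summaries: Sequence[WearDaySummary]) -> pd.DataFrame:
    """Valid-day adherence by follow-up day.

    Day indices count from each participant's first valid day (index 0).
    For each index the frame reports how many participants contributed a
    valid day plus the mean and SD of worn minutes among those valid
    days (SD is NaN when only one participant contributes).
    """
    per: dict[str, list[WearDaySummary]] = {}
    for s in day_summaries:
        per.setdefault(s.participant.participant_id, []).append(s)

    records: list[tuple[int, int]] = []  # (day_index, worn_epochs) over valid days
    for pid, summaries in per.items():
        valid = sorted((s for s in summaries if s.is_valid_day), key=lambda s: s.calendar_date)
        if not valid:
            continue
        first = valid[0].calendar_date
        for s in valid:
            records.append(((s.calendar_date - first).days, s.worn_epochs))

    if not records:
        return pd.DataFrame(
            columns=["followup_day", "n_participants_valid", "worn_minutes_mean", "worn_minutes_sd"]
        )
    df = pd.DataFrame(records, columns=["followup_day", "worn_epochs"])
    out = (
        df.groupby("followup_day")["worn_epochs"]
        .agg(n_participants_valid="count", worn_minutes_mean="mean", worn_minutes_sd="std")
        .reset_index()
    )
    out["n_participants_valid"] = out["n_participants_valid"].astype(int)
    return out
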