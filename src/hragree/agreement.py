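"""Agreement statistics on paired 1-min epochs.

Two devices measure the same minutes; how well do they agree in absolute
terms? This module provides:

* mean difference (test − reference) with paired-t inference,
* the single-measure two-way absolute-agreement intraclass correlation,
  ICC(A,1) in McGraw & Wong's nomenclature, with its F-based 95% CI,
* Bland-Altman bias and limits of agreement,
* stratified variants (by intensity zone, by participant, or any custom
  stratifier), and
* decile box-plot summaries of the paired epochs.

The ICC treats minutes as subjects (rows) and the two devices as raters
(columns) in a two-way ANOVA without replication:

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

where MSR, MSC and MSE are the row (subject), column (device) and residual
mean squares, n the number of minutes and k = 2 devices. Because the
column effect stays in the denominator, a systematic offset between the
devices lowers the coefficient — unlike the consistency form, which
forgives calibration bias. The "overall" figure pools epochs across
participants; per-participant coefficients are available via
stratification. Pooling ignores within-participant autocorrelation of
consecutive minutes, which makes the paired-t inference anticonservative;
this mirrors the common practice in device-validation studies and is
documented as a limitation rather than corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
from scipy import stats

from .epoching import PairedEpoch
from .errors import DegenerateDataError, InsufficientDataError
from .hr_zones import DEFAULT_SCHEME, Zone, ZoneScheme, classify_zone

__all__ = [
    "MeanDifferenceResult",
    "ICCResult",
    "BlandAltmanResult",
    "DecileSummary",
    "AgreementResult",
    "mean_difference",
    "icc_a1",
    "icc_consistency",
    "bland_altman",
    "icc_strength",
    "stratified_agreement",
    "zone_stratifier",
    "participant_stratifier",
    "decile_summary",
    "agreement_suite",
]

_MIN_N_MEAN_DIFF = 2
_MIN_N_ICC = 3


@dataclass(frozen=True)
class MeanDifferenceResult:
    """Paired-t summary of test − reference differences.

    When the differences are constant the standard error is 0 and the t
    statistic and p value are undefined; they are reported as NaN with
    ``degenerate`` set, never silently as 0 or 1.
    """

    n: int
    mean_diff_bpm: float
    se_bpm: float
    ci95: tuple[float, float]
    t_statistic: float
    p_value: float

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.t_statistic)


@dataclass(frozen=True)
class ICCResult:
    n_subjects: int
    k_raters: int
    icc: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    strength_label: str


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement, plus plot-ready coordinates."""

    n: int
    bias_bpm: float
    sd_diff_bpm: float
    loa_lower_bpm: float
    loa_upper_bpm: float
    pair_means_bpm: tuple[float, ...]
    pair_diffs_bpm: tuple[float, ...]


@dataclass(frozen=True)
class AgreementResult:
    """The three agreement statistics for one stratum of paired epochs.

    Any component whose sample-size minimum is not met is None, with the
    reason recorded in ``notes`` — strata are reported as insufficient,
    never silently dropped.
    """

    n: int
    mean_difference: MeanDifferenceResult | None
    icc: ICCResult | None
    bland_altman: BlandAltmanResult | None
    notes: tuple[str, ...] = ()


def _diffs(pairs: Sequence[PairedEpoch]) -> np.ndarray:
    return np.array([p.difference_bpm for p in pairs], dtype=float)


def mean_difference(pairs: Sequence[PairedEpoch]) -> MeanDifferenceResult:
    """Mean of (test − reference) with paired-t 95% CI and p value."""
    n = len(pairs)
    if n < _MIN_N_MEAN_DIFF:
        raise InsufficientDataError(f"mean_difference needs >= {_MIN_N_MEAN_DIFF} pairs, got {n}")
    d = _diffs(pairs)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    if se == 0.0:
        return MeanDifferenceResult(n, mean, 0.0, (mean, mean), math.nan, math.nan)
    tq = stats.t.ppf(0.975, n - 1)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    return MeanDifferenceResult(n, mean, se, (mean - tq * se, mean + tq * se), t_stat, float(p))


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Row, column and residual mean squares of an n×k table (no replication)."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def _icc_a1_ci(
    msr: float, msc: float, mse: float, n: int, k: int, icc: float, alpha: float = 0.05
) -> tuple[float, float]:
    """F-based confidence interval for ICC(A,1) (McGraw & Wong procedure)."""
    if icc >= 1.0 or (msr == 0 and mse == 0):
        return (icc, icc)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (msr - f_l * mse)) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_u * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return (min(lower, icc), max(upper, icc))


def icc_from_table(table: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) from an explicit subjects × raters table of measurements."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters table")
    n, k = table.shape
    if n < _MIN_N_ICC:
        raise InsufficientDataError(f"ICC needs >= {_MIN_N_ICC} subjects, got {n}")
    if np.ptp(table) == 0:
        raise DegenerateDataError("ICC undefined: table has zero total variance")
    msr, msc, mse = _two_way_mean_squares(table)
    denom = msr + (k - 1.0) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("ICC undefined: zero denominator")
    icc = (msr - mse) / denom
    ci = _icc_a1_ci(msr, msc, mse, n, k, icc, alpha)
    return ICCResult(
        n_subjects=n,
        k_raters=k,
        icc=float(icc),
        ci95=(float(ci[0]), float(ci[1])),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        strength_label=icc_strength(icc),
    )


def icc_a1(pairs: Sequence[PairedEpoch]) -> ICCResult:
    """Two-way absolute-agreement single-measure ICC of test vs reference.

    Subjects are the paired minutes (pooled across participants if the
    input spans several); raters are the two devices.
    """
    if len(pairs) < _MIN_N_ICC:
        raise InsufficientDataError(f"ICC needs >= {_MIN_N_ICC} paired epochs, got {len(pairs)}")
    table = np.column_stack(
        [
            [p.test_bpm for p in pairs],
            [p.reference_mean_bpm for p in pairs],
        ]
    )
    return icc_from_table(table)


def icc_consistency(pairs: Sequence[PairedEpoch]) -> float:
    """Consistency-form ICC(C,1) on the same layout (bias-insensitive).

    Exposed for comparison only: absolute agreement is the primary
    statistic, and ICC(A,1) <= ICC(C,1) whenever the devices differ by a
    systematic offset.
    """
    if len(pairs) < _MIN_N_ICC:
        raise InsufficientDataError(f"ICC needs >= {_MIN_N_ICC} paired epochs")
    table = np.column_stack(
        [[p.test_bpm for p in pairs], [p.reference_mean_bpm for p in pairs]]
    )
    n, k = table.shape
    if np.ptp(table) == 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    msr, _msc, mse = _two_way_mean_squares(table)
    return float((msr - mse) / (msr + (k - 1.0) * mse))


def bland_altman(pairs: Sequence[PairedEpoch]) -> BlandAltmanResult:
    """Bias and conventional large-n 95% limits (bias ± 1.96 SD)."""
    n = len(pairs)
    if n < _MIN_N_MEAN_DIFF:
        raise InsufficientDataError(f"bland_altman needs >= {_MIN_N_MEAN_DIFF} pairs, got {n}")
    d = _diffs(pairs)
    means = np.array([(p.test_bpm + p.reference_mean_bpm) / 2.0 for p in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        n=n,
        bias_bpm=bias,
        sd_diff_bpm=sd,
        loa_lower_bpm=bias - 1.96 * sd,
        loa_upper_bpm=bias + 1.96 * sd,
        pair_means_bpm=tuple(float(m) for m in means),
        pair_diffs_bpm=tuple(float(x) for x in d),
    )


def icc_strength(icc: float) -> str:
    """Interpretive label: weak below .5, strong above .7, else moderate.

    The closed interval [.5, .7] is moderate, so the boundary values .5
    and .7 both read as moderate.
    """
    if icc < 0.5:
        return "weak"
    if icc > 0.7:
        return "strong"
    return "moderate"


def agreement_suite(pairs: Sequence[PairedEpoch]) -> AgreementResult:
    """All three agreement statistics, degrading gracefully on small n."""
    n = len(pairs)
    notes: list[str] = []
    md = ba = icc = None
    if n >= _MIN_N_MEAN_DIFF:
        md = mean_difference(pairs)
        ba = bland_altman(pairs)
    else:
        notes.append(f"n={n} < {_MIN_N_MEAN_DIFF}: mean difference and Bland-Altman omitted")
    if n >= _MIN_N_ICC:
        try:
            icc = icc_a1(pairs)
        except DegenerateDataError as exc:
            notes.append(f"ICC degenerate: {exc}")
    else:
        notes.append(f"n={n} < {_MIN_N_ICC}: ICC omitted")
    return AgreementResult(n=n, mean_difference=md, icc=icc, bland_altman=ba, notes=tuple(notes))


def zone_stratifier(
    scheme: ZoneScheme = DEFAULT_SCHEME,
) -> Callable[[PairedEpoch], Zone]:
    """Stratify by intensity zone of the *reference* value.

    The reference device defines the zone (it is the ground truth for
    intensity); the test device's own zone matters only for the
    detection contingency table, not for stratified agreement.
    """

    def _strat(pair: PairedEpoch) -> Zone:
        return classify_zone(pair.reference_mean_bpm, pair.participant.age_years, scheme)

    return _strat


def participant_stratifier(pair: PairedEpoch) -> str:
    return pair.participant.participant_id


def stratified_agreement(
    pairs: Sequence[PairedEpoch],
    strata_fn: Callable[[PairedEpoch], Hashable],
) -> dict[Hashable, AgreementResult]:
    """Agreement statistics per stratum; every pair maps to exactly one."""
    groups: dict[Hashable, list[PairedEpoch]] = {}
    for p in pairs:
        groups.setdefault(strata_fn(p), []).append(p)
    return {label: agreement_suite(group) for label, group in groups.items()}


@dataclass(frozen=True)
class DecileSummary:
    """Box-plot-ready five-number summaries per reference-ranked decile.

    Pairs are rank-ordered by reference mean (ties broken by start time
    then participant id), split into 10 near-equal groups, and each
    group summarised as (min, Q1, median, Q3, max) for the reference
    means, the test values and the reference within-minute range widths.
    """

    n: int
    decile_sizes: tuple[int, ...]
    boundaries_bpm: tuple[float, ...]  # max reference mean per decile
    reference: tuple[tuple[float, float, float, float, float], ...]
    test: tuple[tuple[float, float, float, float, float], ...]
    range_width: tuple[tuple[float, float, float, float, float], ...]


def _five_number(x: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return (float(x.min()), float(q1), float(med), float(q3), float(x.max()))


def decile_summary(pairs: Sequence[PairedEpoch]) -> DecileSummary:
    n = len(pairs)
    if n < 10:
        raise InsufficientDataError(f"decile_summary needs >= 10 pairs, got {n}")
    ordered = sorted(
        pairs,
        key=lambda p: (p.reference_mean_bpm, p.start, p.participant.participant_id),
    )
    groups = np.array_split(np.arange(n), 10)
    ref = np.array([p.reference_mean_bpm for p in ordered])
    tst = np.array([p.test_bpm for p in ordered])
    rw = np.array([p.reference_range_width_bpm for p in ordered])
    return DecileSummary(
        n=n,
        decile_sizes=tuple(len(g) for g in groups),
        boundaries_bpm=tuple(float(ref[g].max()) for g in groups),
        reference=tuple(_five_number(ref[g]) for g in groups),
        test=tuple(_five_number(tst[g]) for g in groups),
        range_width=tuple(_five_number(rw[g]) for g in groups),
    )
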