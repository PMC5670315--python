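"""End-to-end pipeline: from stream CSVs on disk to report tables.

Two entry points mirror the two halves of a tracker-validation study:

``run_validation``
    Pairs each participant's test and reference streams on common-wear
    minutes, then emits the full agreement bundle: an agreement table
    (overall, per intensity zone, per participant), the MVPA-detection
    contingency table with diagnostic metrics, Bland-Altman summaries and
    point coordinates per zone, the decile box-plot table, the raw paired
    epochs, and an epoch-accounting (attrition) record.

``run_freeliving``
    Summarises the follow-up test-only streams into per-day wear records,
    per-participant and pooled zone-minute tables, and the adherence
    curve.

Outputs are plain CSV/JSON, deterministic given the inputs (no
timestamps, no float jitter), and every printed count is a sum of its
documented constituents. Participants whose files are missing are
reported as excluded, never silently dropped.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import agreement, epoching, mvpa_detection, stream_io
from .agreement import AgreementResult
from .epoching import PairedEpoch, WearDaySummary
from .errors import ConfigError
from .hr_zones import Zone, ZoneScheme
from .stream_io import DeviceRole, Participant

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_validation", "run_freeliving"]


class PipelineConfig(BaseModel):
    """Declarative pipeline configuration; defaults are the study rules."""

    data_dir: Path
    out_dir: Path
    max_hr_intercept: float = 220.0
    mvpa_threshold_fraction: float = Field(default=0.50, gt=0.0, lt=1.0)
    min_reference_samples: int = Field(default=1, ge=1, le=6)
    valid_day_min_epochs: int = Field(default=600, ge=1, le=1440)

    @property
    def zone_scheme(self) -> ZoneScheme:
        return ZoneScheme(self.max_hr_intercept, self.mvpa_threshold_fraction)


def _load_participants(config: PipelineConfig) -> list[Participant]:
    path = config.data_dir / "participants.csv"
    if not path.exists():
        raise ConfigError(f"participant table not found: {path}")
    return stream_io.read_participants(path)


def _maybe_stream(
    config: PipelineConfig,
    kind: str,
    participant: Participant,
    role: DeviceRole,
    registry: Sequence[Participant],
):
    path = config.data_dir / f"{kind}_{participant.participant_id}.csv"
    if not path.exists():
        return None
    return stream_io.read_stream(path, role, registry)


def _fmt(x: float | None, nd: int = 4) -> float | str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return round(x, nd)


def _agreement_row(stratum: str, res: AgreementResult) -> dict:
    md, icc = res.mean_difference, res.icc
    return {
        "stratum": stratum,
        "n": res.n,
        "icc": _fmt(icc.icc) if icc else "",
        "icc_ci_low": _fmt(icc.ci95[0]) if icc else "",
        "icc_ci_high": _fmt(icc.ci95[1]) if icc else "",
        "icc_strength": icc.strength_label if icc else "",
        "mean_diff_bpm": _fmt(md.mean_diff_bpm) if md else "",
        "mean_diff_ci_low": _fmt(md.ci95[0]) if md else "",
        "mean_diff_ci_high": _fmt(md.ci95[1]) if md else "",
        "p_value": _fmt(md.p_value, 6) if md else "",
        "notes": "; ".join(res.notes),
    }


def run_validation(config: PipelineConfig) -> dict:
    """Run the paired-session analysis; returns the bundle as dict of frames.

    Also writes everything under ``config.out_dir``. Keys: ``agreement``,
    ``contingency``, ``bland_altman``, ``bland_altman_points``,
    ``deciles``, ``pairs``, ``attrition``.
    """
    participants = _load_participants(config)
    scheme = config.zone_scheme
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    all_pairs: list[PairedEpoch] = []
    attrition: dict = {"participants": {}, "excluded": []}
    for p in participants:
        test = _maybe_stream(config, "validation_test", p, DeviceRole.TEST, participants)
        ref = _maybe_stream(config, "validation_reference", p, DeviceRole.REFERENCE, participants)
        if test is None or ref is None:
            missing = [k for k, s in (("test", test), ("reference", ref)) if s is None]
            attrition["excluded"].append(
                {"participant_id": p.participant_id, "missing": missing}
            )
            logger.warning("participant %s excluded: missing %s stream(s)",
                           p.participant_id, ",".join(missing))
            continue
        pairs = epoching.pair_streams(test, ref, config.min_reference_samples)
        # "possible" epochs: minutes spanned by either device's stream
        spans = []
        for s in (test, ref):
            if s.samples:
                spans.append(
                    (
                        epoching.floor_minute(s.samples[0].timestamp),
                        epoching.floor_minute(s.samples[-1].timestamp),
                    )
                )
        possible = 0
        if spans:
            lo = min(a for a, _ in spans)
            hi = max(b for _, b in spans)
            possible = int((hi - lo).total_seconds() // 60) + 1
        attrition["participants"][p.participant_id] = {
            "possible_epochs": possible,
            "paired_epochs": len(pairs),
        }
        logger.info("participant %s: %d possible epochs -> %d paired",
                    p.participant_id, possible, len(pairs))
        all_pairs.extend(pairs)

    attrition["total_possible_epochs"] = sum(
        v["possible_epochs"] for v in attrition["participants"].values()
    )
    attrition["total_paired_epochs"] = len(all_pairs)

    # agreement table: overall, by zone, by participant
    rows = [_agreement_row("overall", agreement.agreement_suite(all_pairs))]
    by_zone = agreement.stratified_agreement(all_pairs, agreement.zone_stratifier(scheme))
    for zone in (Zone.LOW, Zone.MVPA):
        res = by_zone.get(zone, AgreementResult(0, None, None, None, ("no epochs",)))
        rows.append(_agreement_row(f"zone_{zone.value}", res))
    by_pid = agreement.stratified_agreement(all_pairs, agreement.participant_stratifier)
    for pid in sorted(by_pid):
        rows.append(_agreement_row(f"participant_{pid}", by_pid[pid]))
    agreement_df = pd.DataFrame(rows)

    # contingency + diagnostics
    table = mvpa_detection.build_contingency(all_pairs, scheme)
    metrics = mvpa_detection.diagnostic_metrics(table)
    contingency_df = pd.DataFrame(
        [
            {
                "ref_low_test_low": table.ref_low_test_low,
                "ref_low_test_mvpa": table.ref_low_test_mvpa,
                "ref_mvpa_test_low": table.ref_mvpa_test_low,
                "ref_mvpa_test_mvpa": table.ref_mvpa_test_mvpa,
                "ref_low_total": table.ref_low_total,
                "ref_mvpa_total": table.ref_mvpa_total,
                "test_low_total": table.test_low_total,
                "test_mvpa_total": table.test_mvpa_total,
                "total": table.total,
                "sensitivity_pct": metrics.sensitivity.percent(1) if metrics.sensitivity else "",
                "specificity_pct": metrics.specificity.percent(1) if metrics.specificity else "",
                "ppv_pct": metrics.ppv.percent(1) if metrics.ppv else "",
                "npv_pct": metrics.npv.percent(2) if metrics.npv else "",
            }
        ]
    )

    # Bland-Altman per zone (plot-ready)
    ba_rows, ba_points = [], []
    for zone in (Zone.LOW, Zone.MVPA):
        res = by_zone.get(zone)
        if res is None or res.bland_altman is None:
            ba_rows.append({"stratum": f"zone_{zone.value}", "n": 0})
            continue
        ba = res.bland_altman
        ba_rows.append(
            {
                "stratum": f"zone_{zone.value}",
                "n": ba.n,
                "bias_bpm": _fmt(ba.bias_bpm),
                "sd_diff_bpm": _fmt(ba.sd_diff_bpm),
                "loa_lower_bpm": _fmt(ba.loa_lower_bpm),
                "loa_upper_bpm": _fmt(ba.loa_upper_bpm),
            }
        )
        for m, d in zip(ba.pair_means_bpm, ba.pair_diffs_bpm):
            ba_points.append(
                {"stratum": f"zone_{zone.value}", "pair_mean_bpm": m, "difference_bpm": d}
            )
    bland_altman_df = pd.DataFrame(ba_rows)
    ba_points_df = pd.DataFrame(ba_points)

    # decile box-plot table
    decile_rows = []
    if len(all_pairs) >= 10:
        dec = agreement.decile_summary(all_pairs)
        for i in range(10):
            for series_name, series in (
                ("reference_mean", dec.reference),
                ("test", dec.test),
                ("reference_range_width", dec.range_width),
            ):
                mn, q1, med, q3, mx = series[i]
                decile_rows.append(
                    {
                        "decile": i + 1,
                        "n": dec.decile_sizes[i],
                        "series": series_name,
                        "min": _fmt(mn),
                        "q1": _fmt(q1),
                        "median": _fmt(med),
                        "q3": _fmt(q3),
                        "max": _fmt(mx),
                    }
                )
    deciles_df = pd.DataFrame(decile_rows)

    pairs_df = epoching.pairs_to_frame(all_pairs)

    bundle = {
        "agreement": agreement_df,
        "contingency": contingency_df,
        "bland_altman": bland_altman_df,
        "bland_altman_points": ba_points_df,
        "deciles": deciles_df,
        "pairs": pairs_df,
        "attrition": attrition,
    }
    agreement_df.to_csv(out / "agreement_table.csv", index=False)
    contingency_df.to_csv(out / "contingency_table.csv", index=False)
    bland_altman_df.to_csv(out / "bland_altman.csv", index=False)
    ba_points_df.to_csv(out / "bland_altman_points.csv", index=False)
    deciles_df.to_csv(out / "decile_summary.csv", index=False)
    pairs_df.to_csv(out / "paired_epochs.csv", index=False)
    (out / "attrition.json").write_text(
        json.dumps(attrition, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return bundle


def run_freeliving(config: PipelineConfig) -> dict:
    """Run the follow-up (test-device-only) analysis and write its tables."""
    participants = _load_participants(config)
    scheme = config.zone_scheme
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    day_summaries: list[WearDaySummary] = []
    excluded = []
    for p in participants:
        stream = _maybe_stream(config, "followup_test", p, DeviceRole.TEST, participants)
        if stream is None:
            excluded.append(p.participant_id)
            logger.warning("participant %s has no follow-up stream", p.participant_id)
            continue
        if not stream.samples:
            logger.warning("participant %s: empty follow-up stream", p.participant_id)
            continue
        day_summaries.extend(
            epoching.daily_wear_summaries(
                stream, scheme, valid_day_min_epochs=config.valid_day_min_epochs
            )
        )

    wear_days_df = epoching.summaries_to_frame(day_summaries)
    per_rows, overall = mvpa_detection.freeliving_summary(day_summaries)

    def _summary_row(s: mvpa_detection.FreeLivingSummary) -> dict:
        return {
            "participant_id": s.participant_id,
            "valid_days": s.valid_days,
            "total_epochs": s.total_epochs,
            "n_noread": s.n_noread,
            "n_low": s.n_low,
            "n_mvpa": s.n_mvpa,
            "pct_noread": _fmt(s.pct_noread, 1) if s.total_epochs else "",
            "pct_low": _fmt(s.pct_low, 1) if s.total_epochs else "",
            "pct_mvpa": _fmt(s.pct_mvpa, 1) if s.total_epochs else "",
            "avg_daily_mvpa_min": _fmt(s.avg_daily_mvpa_min, 2) if s.valid_days else "",
            "avg_daily_mvpa_min_display": (
                s.avg_daily_mvpa_min_display if s.valid_days else ""
            ),
        }

    summary_df = pd.DataFrame([_summary_row(s) for s in per_rows] + [_summary_row(overall)])
    adherence_df = mvpa_detection.adherence_curve(day_summaries)

    wear_days_df.to_csv(out / "wear_days.csv", index=False)
    summary_df.to_csv(out / "freeliving_summary.csv", index=False)
    adherence_df.to_csv(out / "adherence_curve.csv", index=False)
    if excluded:
        (out / "freeliving_excluded.json").write_text(
            json.dumps({"excluded": excluded}, indent=2) + "\n", encoding="utf-8"
        )
    return {
        "wear_days": wear_days_df,
        "freeliving_summary": summary_df,
        "adherence_curve": adherence_df,
        "excluded": excluded,
    }
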