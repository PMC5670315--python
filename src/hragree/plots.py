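"""Optional figure rendering.

The pipeline's contract is the plot-ready data tables it always writes;
these helpers turn those tables into conventional figures when
matplotlib is available. Importing this module without matplotlib
installed raises ImportError at call time, not import time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .agreement import BlandAltmanResult, DecileSummary
from .epoching import PairedEpoch


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("figure rendering requires matplotlib (extra 'plots')") from exc
    return plt


def bland_altman_plot(result: BlandAltmanResult, path: str | Path, title: str = "") -> None:
    """Scatter of per-pair differences against per-pair means with bias and
    95% limits of agreement."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.pair_means_bpm, result.pair_diffs_bpm, s=8, alpha=0.4, color="k")
    for y, style in ((result.bias_bpm, "-"), (result.loa_lower_bpm, "--"),
                     (result.loa_upper_bpm, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("Mean of devices (bpm)")
    ax.set_ylabel("Test − reference (bpm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def decile_boxplot(summary: DecileSummary, path: str | Path) -> None:
    """Side-by-side five-number boxes per decile: reference means, test
    values, and reference within-minute range widths."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    series = (("reference", summary.reference, "0.5"),
              ("test", summary.test, "0.1"),
              ("range width", summary.range_width, "1.0"))
    width = 0.25
    for offset, (label, fives, shade) in zip((-width, 0.0, width), series):
        stats = [
            {"whislo": mn, "q1": q1, "med": med, "q3": q3, "whishi": mx, "fliers": []}
            for (mn, q1, med, q3, mx) in fives
        ]
        ax.bxp(
            stats,
            positions=[i + 1 + offset for i in range(10)],
            widths=width * 0.9,
            showfliers=False,
            patch_artist=True,
            boxprops={"facecolor": shade},
            label=label,
        )
    ax.set_xticks(range(1, 11))
    ax.set_xticklabels([str(i) for i in range(1, 11)])
    ax.set_xlabel("Decile of reference mean")
    ax.set_ylabel("Heart rate (bpm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def adherence_plot(curve: pd.DataFrame, path: str | Path) -> None:
    """Bars of participants contributing a valid day per follow-up day with
    mean ± SD worn minutes overlaid."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(curve["followup_day"], curve["n_participants_valid"], color="0.7",
           label="participants with valid day")
    ax.set_xlabel("Follow-up day")
    ax.set_ylabel("Participants")
    ax2 = ax.twinx()
    ax2.errorbar(
        curve["followup_day"],
        curve["worn_minutes_mean"],
        yerr=curve["worn_minutes_sd"].fillna(0.0),
        fmt="o",
        color="k",
        markersize=3,
        capsize=2,
        label="worn minutes (mean ± SD)",
    )
    ax2.set_ylabel("Worn minutes on valid days")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def timeseries_plot(pairs: Sequence[PairedEpoch], path: str | Path, title: str = "") -> None:
    """Test readings over reference per-minute ranges for one participant."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(9, 3.5))
    starts = [p.start for p in pairs]
    ref = [p.reference_mean_bpm for p in pairs]
    half = [p.reference_range_width_bpm / 2 for p in pairs]
    ax.errorbar(starts, ref, yerr=half, fmt="none", ecolor="0.7",
                label="reference minute range")
    ax.plot(starts, [p.test_bpm for p in pairs], "ko", markersize=3, label="test")
    ax.set_ylabel("Heart rate (bpm)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
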