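"""Age-based heart-rate zone classification.

Relative exercise intensity is expressed as a fraction of the age-predicted
maximal heart rate, ``HRmax = 220 - age`` (bpm). A 1-min epoch whose heart
rate reaches at least 50% of HRmax is classed as moderate-to-vigorous
physical activity (MVPA); anything below is "low". The 50% boundary itself
is MVPA. Only these two strata exist: the scheme deliberately collapses
moderate, vigorous and maximal intensities into one MVPA stratum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import UndefinedInputError

__all__ = [
    "Zone",
    "ZoneScheme",
    "max_heart_rate",
    "relative_intensity",
    "classify_zone",
    "mvpa_cutoff_bpm",
]


class Zone(str, enum.Enum):
    """Intensity stratum of a single epoch. Exhaustive for any positive HR."""

    LOW = "low"
    MVPA = "mvpa"


@dataclass(frozen=True)
class ZoneScheme:
    """Parameters of the age-based zone rule.

    Parameters
    ----------
    max_hr_intercept : float
        Intercept of the age-predicted maximal heart rate formula, bpm.
        HRmax = ``max_hr_intercept - age_years``.
    mvpa_threshold_fraction : float
        Fraction of HRmax at or above which an epoch counts as MVPA.
        Must lie strictly between 0 and 1.
    """

    max_hr_intercept: float = 220.0
    mvpa_threshold_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.mvpa_threshold_fraction < 1.0:
            raise ValueError(
                "mvpa_threshold_fraction must be in (0, 1), got "
                f"{self.mvpa_threshold_fraction}"
            )


#: The default scheme: HRmax = 220 - age, MVPA at >= 50% of HRmax.
DEFAULT_SCHEME = ZoneScheme()


def max_heart_rate(age_years: float, scheme: ZoneScheme = DEFAULT_SCHEME) -> float:
    """Age-predicted maximal heart rate in bpm. Not rounded."""
    return scheme.max_hr_intercept - age_years


def mvpa_cutoff_bpm(age_years: float, scheme: ZoneScheme = DEFAULT_SCHEME) -> float:
    """Absolute heart rate (bpm) at the LOW -> MVPA boundary for this age."""
    return scheme.mvpa_threshold_fraction * max_heart_rate(age_years, scheme)


def relative_intensity(
    hr_bpm: float, age_years: float, scheme: ZoneScheme = DEFAULT_SCHEME
) -> float:
    """Heart rate as a fraction of age-predicted HRmax.

    May exceed 1 for readings above the predicted maximum. A zero heart
    rate encodes "no reading" upstream and has no intensity; passing it
    here raises :class:`UndefinedInputError`.
    """
    if hr_bpm <= 0:
        raise UndefinedInputError(
            f"relative intensity undefined for hr_bpm={hr_bpm}; "
            "zero encodes nonwear and must be filtered upstream"
        )
    return hr_bpm / max_heart_rate(age_years, scheme)


def classify_zone(
    hr_bpm: float, age_years: float, scheme: ZoneScheme = DEFAULT_SCHEME
) -> Zone:
    """Classify a positive heart rate into LOW or MVPA.

    The threshold is inclusive: exactly ``mvpa_threshold_fraction`` of
    HRmax classifies as MVPA.
    """
    frac = relative_intensity(hr_bpm, age_years, scheme)
    return Zone.MVPA if frac >= scheme.mvpa_threshold_fraction else Zone.LOW
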