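"""Reading, validating and writing heart-rate streams and participant metadata.

File dialect
------------
Streams are long-format CSV with header ``participant_id,timestamp,hr_bpm``:
one row per sample, timestamps ISO-8601 local time without timezone
(``YYYY-MM-DDTHH:MM:SS``), heart rate as a non-negative integer. A value of
0 is the single "no valid reading" encoding (device off-wrist or dropout);
absent rows mean the same thing for the missing instants. Values above
250 bpm are rejected as corrupt — that is above the age-predicted maximum
for any adult.

Participant metadata is a CSV with header ``participant_id,age_years`` and
an optional third ``label`` column (display letters in the A-J style).

The writer and reader are exact inverses: integers and second-resolution
timestamps round-trip bit-identically.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    AgeRangeError,
    HeartRateRangeError,
    RegistryError,
    StreamFormatError,
    StreamOrderingError,
)

__all__ = [
    "DeviceRole",
    "Participant",
    "HeartRateSample",
    "SensorStream",
    "read_stream",
    "write_stream",
    "read_participants",
    "write_participants",
]

STREAM_HEADER = ["participant_id", "timestamp", "hr_bpm"]
PARTICIPANT_HEADER = ["participant_id", "age_years"]
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

HR_MIN = 0
HR_MAX = 250
AGE_MIN = 18.0
AGE_MAX = 120.0


class DeviceRole(str, enum.Enum):
    """Which side of the comparison a device sits on."""

    TEST = "test"  # wrist tracker, 60-s sampling
    REFERENCE = "reference"  # chest strap, 10-s sampling


#: Nominal sampling interval (seconds) implied by each role.
ROLE_INTERVALS: Mapping[DeviceRole, int] = {
    DeviceRole.TEST: 60,
    DeviceRole.REFERENCE: 10,
}


@dataclass(frozen=True)
class Participant:
    """One study participant.

    ``age_years`` may be fractional and is used unrounded by the zone
    formula. Ages outside [18, 120] are rejected: the study population is
    adult, and anything above 120 is presumed a data error.
    """

    participant_id: str
    age_years: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise RegistryError("participant_id must be a non-empty string")
        if not AGE_MIN <= self.age_years <= AGE_MAX:
            raise AgeRangeError(
                f"age_years={self.age_years} outside [{AGE_MIN}, {AGE_MAX}] "
                f"for participant {self.participant_id!r}"
            )


@dataclass(frozen=True)
class HeartRateSample:
    """A single timestamped reading; ``hr_bpm == 0`` means no valid reading."""

    timestamp: datetime
    hr_bpm: int

    def __post_init__(self) -> None:
        if not HR_MIN <= self.hr_bpm <= HR_MAX:
            raise HeartRateRangeError(
                f"hr_bpm={self.hr_bpm} outside [{HR_MIN}, {HR_MAX}] at {self.timestamp}"
            )


@dataclass(frozen=True)
class SensorStream:
    """Ordered heart-rate samples from one device on one participant."""

    participant: Participant
    device_role: DeviceRole
    samples: tuple[HeartRateSample, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        prev: datetime | None = None
        for s in self.samples:
            if prev is not None and s.timestamp <= prev:
                raise StreamOrderingError(
                    f"timestamps not strictly increasing: {prev} then {s.timestamp} "
                    f"(participant {self.participant.participant_id!r})"
                )
            prev = s.timestamp

    @property
    def nominal_interval_s(self) -> int:
        return ROLE_INTERVALS[self.device_role]

    def __len__(self) -> int:
        return len(self.samples)

    def timestamps(self) -> list[datetime]:
        return [s.timestamp for s in self.samples]

    def values(self) -> list[int]:
        return [s.hr_bpm for s in self.samples]


def _require_header(actual: Sequence[str] | None, expected: Sequence[str], path: Path,
                    optional_tail: Sequence[str] = ()) -> None:
    if actual is None:
        raise StreamFormatError(f"{path}: empty file, expected header {expected}")
    actual = [c.strip() for c in actual]
    allowed = [list(expected)] + [
        list(expected) + list(optional_tail[: i + 1]) for i in range(len(optional_tail))
    ]
    if actual not in allowed:
        raise StreamFormatError(
            f"{path}: header {actual} does not match required {list(expected)}"
        )


def read_stream(
    path: str | Path,
    device_role: DeviceRole | str,
    participant_registry: Iterable[Participant],
) -> SensorStream:
    """Read one device stream from CSV.

    Parameters
    ----------
    path : path to a stream CSV (dialect above); all rows must belong to a
        single participant present in ``participant_registry``.
    device_role : ``"test"`` or ``"reference"`` (or the enum).
    participant_registry : the known participants; rows naming anyone else
        raise :class:`RegistryError`.

    Raises
    ------
    StreamFormatError, StreamOrderingError, HeartRateRangeError, RegistryError
        Malformed files are rejected, never silently repaired; in
        particular duplicate timestamps are an ordering error, not a
        deduplication opportunity.
    """
    path = Path(path)
    role = DeviceRole(device_role)
    registry = {p.participant_id: p for p in participant_registry}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _require_header(header, STREAM_HEADER, path)

        samples: list[HeartRateSample] = []
        pid: str | None = None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise StreamFormatError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            row_pid, ts_text, hr_text = (c.strip() for c in row)
            if pid is None:
                pid = row_pid
                if pid not in registry:
                    raise RegistryError(f"{path}:{lineno}: unknown participant_id {pid!r}")
            elif row_pid != pid:
                raise StreamFormatError(
                    f"{path}:{lineno}: mixed participant ids ({pid!r} and {row_pid!r}) "
                    "in one stream file"
                )
            try:
                ts = datetime.strptime(ts_text, TIMESTAMP_FORMAT)
            except ValueError as exc:
                raise StreamFormatError(f"{path}:{lineno}: bad timestamp {ts_text!r}") from exc
            try:
                hr = int(hr_text)
            except ValueError as exc:
                raise StreamFormatError(f"{path}:{lineno}: bad hr_bpm {hr_text!r}") from exc
            samples.append(HeartRateSample(ts, hr))

    if pid is None:
        raise StreamFormatError(f"{path}: stream file contains a header but no rows")
    return SensorStream(registry[pid], role, tuple(samples))


def write_stream(stream: SensorStream, path: str | Path) -> None:
    """Write a stream in the package CSV dialect (exact round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(STREAM_HEADER)
        pid = stream.participant.participant_id
        for s in stream.samples:
            writer.writerow([pid, s.timestamp.strftime(TIMESTAMP_FORMAT), s.hr_bpm])


def read_participants(path: str | Path) -> list[Participant]:
    """Read the participant metadata table; ids must be unique."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _require_header(header, PARTICIPANT_HEADER, path, optional_tail=("label",))
        has_label = header is not None and len([c for c in header if c.strip()]) == 3

        out: list[Participant] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            expected_n = 3 if has_label else 2
            if len(row) != expected_n:
                raise StreamFormatError(
                    f"{path}:{lineno}: expected {expected_n} fields, got {len(row)}"
                )
            pid = row[0].strip()
            if pid in seen:
                raise RegistryError(f"{path}:{lineno}: duplicate participant_id {pid!r}")
            seen.add(pid)
            try:
                age = float(row[1])
            except ValueError as exc:
                raise StreamFormatError(f"{path}:{lineno}: bad age_years {row[1]!r}") from exc
            label = row[2].strip() if has_label else None
            out.append(Participant(pid, age, label or None))
    return out


def write_participants(participants: Sequence[Participant], path: str | Path) -> None:
    has_label = any(p.label for p in participants)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PARTICIPANT_HEADER + (["label"] if has_label else []))
        for p in participants:
            age = int(p.age_years) if float(p.age_years).is_integer() else p.age_years
            row = [p.participant_id, age]
            if has_label:
                row.append(p.label or "")
            writer.writerow(row)
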