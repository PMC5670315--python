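"""Shared fixtures and test helpers."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import settings

from hragree.epoching import PairedEpoch
from hragree.stream_io import (
    DeviceRole,
    HeartRateSample,
    Participant,
    SensorStream,
)

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")

T0 = datetime(2024, 3, 4, 10, 0, 0)


@pytest.fixture
def participant() -> Participant:
    return Participant("P01", 25.0, label="A")


def make_stream(
    participant: Participant,
    values,
    role: DeviceRole = DeviceRole.TEST,
    start: datetime = T0,
    step_s: int = 60,
) -> SensorStream:
    """Stream with one sample per ``step_s`` seconds, values in order."""
    samples = tuple(
        HeartRateSample(start + timedelta(seconds=i * step_s), v) for i, v in enumerate(values)
    )
    return SensorStream(participant, role, samples)


def make_pairs(test_values, reference_values, participant: Participant | None = None,
               start: datetime = T0) -> list[PairedEpoch]:
    """Paired epochs on consecutive minutes from two value sequences."""
    p = participant or Participant("P01", 25.0)
    assert len(test_values) == len(reference_values)
    return [
        PairedEpoch(
            participant=p,
            start=start + timedelta(minutes=i),
            test_bpm=float(t),
            reference_mean_bpm=float(r),
            reference_range_width_bpm=0.0,
        )
        for i, (t, r) in enumerate(zip(test_values, reference_values))
    ]
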