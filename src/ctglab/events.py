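"""Detection of FHR accelerations/decelerations and uterine contractions.

An acceleration is a maximal run of samples strictly above the baseline
whose maximum deviation exceeds 15 bpm, whose mean deviation exceeds
10 bpm, and (following the FIGO 15-s rule) lasting at least 15 s;
decelerations are the mirror image below the baseline.  Decelerations
lasting more than two minutes are flagged *late*.  Contractions are
maximal runs of the uterine-activity trace above 10 mm Hg lasting more
than 30 s.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import AlignmentError
from .types import Event, EventKind, as_float_array

ACCEL_MAX_DEV_BPM = 15.0
ACCEL_MEAN_DEV_BPM = 10.0
LATE_DECEL_MIN_S = 120.0
CONTRACTION_THRESHOLD_MMHG = 10.0


def _positive_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _detect_excursions(
    deviation: np.ndarray,
    sample_rate: float,
    kind: EventKind,
    min_duration_s: float,
    max_dev: float,
    mean_dev: float,
) -> list[Event]:
    dt = 1.0 / sample_rate
    events = []
    for start, end in _positive_runs(deviation > 0):
        dev = deviation[start:end]
        duration = (end - start) * dt
        if duration < min_duration_s:
            continue
        if dev.max() <= max_dev or dev.mean() <= mean_dev:
            continue
        peak = start + int(np.argmax(dev))
        events.append(
            Event(
                kind=kind,
                start_s=start * dt,
                end_s=end * dt,
                peak_s=peak * dt,
                max_depth=float(dev.max()),
                area=float(dev.sum() * dt),
                is_late=(kind is EventKind.DECELERATION and duration > LATE_DECEL_MIN_S),
            )
        )
    return events


def detect_accelerations(
    fhr: np.ndarray,
    baseline: np.ndarray,
    sample_rate: float = 4.0,
    min_duration_s: float = 15.0,
) -> list[Event]:
    """Accelerations in a gap-free segment given its baseline.

    Candidate periods are maximal runs with ``fhr > baseline`` (samples
    equal to the baseline break runs); a run qualifies when max deviation
    > 15 bpm, mean deviation > 10 bpm, and duration >= ``min_duration_s``.
    Areas are time integrals in bpm*s.
    """
    f = as_float_array(fhr)
    b = as_float_array(baseline)
    if f.shape != b.shape:
        raise AlignmentError("fhr and baseline must have the same length")
    return _detect_excursions(
        f - b, sample_rate, EventKind.ACCELERATION, min_duration_s,
        ACCEL_MAX_DEV_BPM, ACCEL_MEAN_DEV_BPM,
    )


def detect_decelerations(
    fhr: np.ndarray,
    baseline: np.ndarray,
    sample_rate: float = 4.0,
    min_duration_s: float = 15.0,
) -> list[Event]:
    """Decelerations: symmetric to accelerations with deviations measured
    as ``baseline - fhr``; runs longer than 2 min are flagged late."""
    f = as_float_array(fhr)
    b = as_float_array(baseline)
    if f.shape != b.shape:
        raise AlignmentError("fhr and baseline must have the same length")
    return _detect_excursions(
        b - f, sample_rate, EventKind.DECELERATION, min_duration_s,
        ACCEL_MAX_DEV_BPM, ACCEL_MEAN_DEV_BPM,
    )


def detect_contractions(
    uc: np.ndarray,
    sample_rate: float = 4.0,
    threshold: float = CONTRACTION_THRESHOLD_MMHG,
    min_duration_s: float = 30.0,
) -> list[Event]:
    """Uterine contractions: maximal runs of UC strictly above ``threshold``
    lasting strictly more than ``min_duration_s``.  Area is integrated above
    the threshold (mmHg*s); depth is the peak excess over the threshold."""
    u = as_float_array(uc)
    dt = 1.0 / sample_rate
    events = []
    for start, end in _positive_runs(u > threshold):
        duration = (end - start) * dt
        if duration <= min_duration_s:
            continue
        excess = u[start:end] - threshold
        peak = start + int(np.argmax(excess))
        events.append(
            Event(
                kind=EventKind.CONTRACTION,
                start_s=start * dt,
                end_s=end * dt,
                peak_s=peak * dt,
                max_depth=float(excess.max()),
                area=float(excess.sum() * dt),
            )
        )
    return events


EVENT_CSV_COLUMNS = ("kind", "start_s", "end_s", "peak_s", "max_depth", "area", "is_late")


def write_events_csv(events: list[Event], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_CSV_COLUMNS)
        for e in sorted(events, key=lambda e: e.start_s):
            writer.writerow(
                [e.kind.value, e.start_s, e.end_s, e.peak_s, e.max_depth, e.area, int(e.is_late)]
            )


def read_events_csv(path: str | Path) -> list[Event]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(
                Event(
                    kind=EventKind(row["kind"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    peak_s=float(row["peak_s"]),
                    max_depth=float(row["max_depth"]),
                    area=float(row["area"]),
                    is_late=bool(int(row["is_late"])),
                )
            )
    return events
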