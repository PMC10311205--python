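"""The 25-feature vector computed on one 30-min CTG segment.

Feature groups: baseline statistics (min / median / max of the estimated
baseline, bpm), acceleration and deceleration summaries (counts, total
durations, areas, maximum depths, with a parallel set for *late*
decelerations lasting > 2 min), contraction summaries, joint
deceleration-contraction features (time and area of decelerations falling
outside contractions; summed peak-to-peak time offsets), and the two
variability indices: short-term variability (STV, mean absolute difference
of successive 3.75-s epoch means) and long-term variability (LTV, mean
per-minute FHR range).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import LengthError
from .events import Event
from .types import BaselineEstimate, Segment, as_float_array

STV_EPOCH_S = 3.75
LTV_EPOCH_S = 60.0

#: Canonical feature order used by exports and models.
FEATURE_NAMES: tuple[str, ...] = (
    "b_min", "b_med", "b_max",
    "acc_count", "acc_total_dur", "acc_area", "acc_max_depth",
    "dec_count", "late_dec_count", "dec_total_dur", "late_dec_total_dur",
    "dec_area", "late_dec_area", "dec_max_depth",
    "ctr_count", "ctr_total_dur", "ctr_area",
    "dec_no_ctr_dur", "late_dec_no_ctr_dur",
    "dec_no_ctr_area", "late_dec_no_ctr_area",
    "dec_ctr_peak_timediff", "late_dec_ctr_peak_timediff",
    "stv", "ltv",
)

DEFAULT_MODEL_FEATURES: tuple[str, ...] = ("b_min", "b_max", "acc_area", "dec_area")


@dataclass(frozen=True)
class FeatureVector:
    b_min: float
    b_med: float
    b_max: float
    acc_count: float
    acc_total_dur: float
    acc_area: float
    acc_max_depth: float
    dec_count: float
    late_dec_count: float
    dec_total_dur: float
    late_dec_total_dur: float
    dec_area: float
    late_dec_area: float
    dec_max_depth: float
    ctr_count: float
    ctr_total_dur: float
    ctr_area: float
    dec_no_ctr_dur: float
    late_dec_no_ctr_dur: float
    dec_no_ctr_area: float
    late_dec_no_ctr_area: float
    dec_ctr_peak_timediff: float
    late_dec_ctr_peak_timediff: float
    stv: float
    ltv: float

    def as_array(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self) -> None:
        for n in ("acc_count", "dec_count", "late_dec_count", "ctr_count"):
            v = getattr(self, n)
            if v < 0 or v != int(v):
                raise ValueError(f"{n}={v} must be a nonnegative integer")
        if not (self.b_min <= self.b_med <= self.b_max):
            raise ValueError("baseline stats must be ordered min <= med <= max")
        for late, full in (
            ("late_dec_count", "dec_count"),
            ("late_dec_total_dur", "dec_total_dur"),
            ("late_dec_area", "dec_area"),
            ("late_dec_no_ctr_dur", "dec_no_ctr_dur"),
            ("late_dec_no_ctr_area", "dec_no_ctr_area"),
        ):
            if getattr(self, late) > getattr(self, full) + 1e-9:
                raise ValueError(f"{late} exceeds {full}")


def compute_stv(fhr: np.ndarray, sample_rate: float = 4.0, epoch_s: float = STV_EPOCH_S) -> float:
    """Mean absolute difference between successive 3.75-s epoch means (bpm).
    Trailing samples that do not fill an epoch are dropped."""
    x = as_float_array(fhr)
    per = int(round(epoch_s * sample_rate))
    n_epochs = x.size // per
    if n_epochs < 2:
        raise LengthError(f"need at least two {epoch_s} s epochs, got {x.size} samples")
    means = x[: n_epochs * per].reshape(n_epochs, per).mean(axis=1)
    return float(np.abs(np.diff(means)).mean())


def compute_ltv(fhr: np.ndarray, sample_rate: float = 4.0, epoch_s: float = LTV_EPOCH_S) -> float:
    """Mean per-minute amplitude (max - min) of the FHR (bpm); partial
    trailing minutes are dropped."""
    x = as_float_array(fhr)
    per = int(round(epoch_s * sample_rate))
    n_epochs = x.size // per
    if n_epochs < 1:
        raise LengthError(f"need at least one full minute, got {x.size} samples")
    chunks = x[: n_epochs * per].reshape(n_epochs, per)
    return float((chunks.max(axis=1) - chunks.min(axis=1)).mean())


def _interval_mask(events: list[Event], n: int, sample_rate: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for e in events:
        lo = int(round(e.start_s * sample_rate))
        hi = int(round(e.end_s * sample_rate))
        mask[max(lo, 0) : min(hi, n)] = True
    return mask


def joint_dec_contraction(
    dec_events: list[Event],
    ctr_events: list[Event],
    fhr: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
    sample_rate: float = 4.0,
) -> dict[str, float]:
    """The six joint deceleration-contraction features.

    Outside-contraction durations/areas are computed on each deceleration
    interval minus the union of contraction intervals (at sample
    resolution; the area keeps only surviving samples, which needs the
    deviation series — when ``fhr``/``baseline`` are not given the area is
    prorated by surviving duration).  Peak-time features sum, over
    decelerations, the absolute offset to the nearest contraction peak;
    they are 0 when the segment has no contraction.
    """
    out = dict.fromkeys(
        (
            "dec_no_ctr_dur", "late_dec_no_ctr_dur",
            "dec_no_ctr_area", "late_dec_no_ctr_area",
            "dec_ctr_peak_timediff", "late_dec_ctr_peak_timediff",
        ),
        0.0,
    )
    dt = 1.0 / sample_rate
    if fhr is not None and baseline is not None:
        deviation = as_float_array(baseline) - as_float_array(fhr)
        n = deviation.size
    else:
        deviation = None
        n = int(round(max((e.end_s for e in dec_events + ctr_events), default=0.0) * sample_rate))
    ctr_mask = _interval_mask(ctr_events, n, sample_rate)
    ctr_peaks = np.array([c.peak_s for c in ctr_events])

    for d in dec_events:
        lo = int(round(d.start_s * sample_rate))
        hi = min(int(round(d.end_s * sample_rate)), n)
        outside = ~ctr_mask[lo:hi]
        dur = float(outside.sum() * dt)
        if deviation is not None:
            area = float(np.clip(deviation[lo:hi][outside], 0, None).sum() * dt)
        else:
            area = d.area * (dur / d.duration_s if d.duration_s > 0 else 0.0)
        out["dec_no_ctr_dur"] += dur
        out["dec_no_ctr_area"] += area
        if ctr_peaks.size:
            td = float(np.min(np.abs(ctr_peaks - d.peak_s)))
            out["dec_ctr_peak_timediff"] += td
        else:
            td = 0.0
        if d.is_late:
            out["late_dec_no_ctr_dur"] += dur
            out["late_dec_no_ctr_area"] += area
            out["late_dec_ctr_peak_timediff"] += td
    return out


def _event_summary(events: list[Event], sample_rate: float) -> tuple[float, float, float, float]:
    """(count, total duration, total area, max depth); zeros when empty."""
    if not events:
        return 0.0, 0.0, 0.0, 0.0
    return (
        float(len(events)),
        float(sum(e.duration_s for e in events)),
        float(sum(e.area for e in events)),
        float(max(e.max_depth for e in events)),
    )


def compute_features(
    segment: Segment,
    baseline: BaselineEstimate,
    accelerations: list[Event],
    decelerations: list[Event],
    contractions: list[Event],
) -> FeatureVector:
    """Assemble the full 25-feature vector for one segment."""
    if baseline.baseline.shape != segment.fhr.shape:
        raise LengthError("baseline does not align with segment")
    b = baseline.baseline
    fs = segment.sample_rate
    acc = _event_summary(accelerations, fs)
    dec = _event_summary(decelerations, fs)
    late = _event_summary([e for e in decelerations if e.is_late], fs)
    ctr = _event_summary(contractions, fs)
    joint = joint_dec_contraction(decelerations, contractions, segment.fhr, b, fs)
    return FeatureVector(
        b_min=float(b.min()),
        b_med=float(np.median(b)),
        b_max=float(b.max()),
        acc_count=acc[0], acc_total_dur=acc[1], acc_area=acc[2], acc_max_depth=acc[3],
        dec_count=dec[0], late_dec_count=late[0],
        dec_total_dur=dec[1], late_dec_total_dur=late[1],
        dec_area=dec[2], late_dec_area=late[2],
        dec_max_depth=dec[3],
        ctr_count=ctr[0], ctr_total_dur=ctr[1], ctr_area=ctr[2],
        stv=compute_stv(segment.fhr, fs),
        ltv=compute_ltv(segment.fhr, fs),
        **joint,
    )
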