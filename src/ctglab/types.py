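"""Core domain types for cardiotocography (CTG) analysis.

A CTG recording pairs a fetal heart rate (FHR) trace in beats per minute
with a uterine activity (UC) trace in mm Hg, both sampled on one time axis
(4 Hz in routine monitors).  Missing points are carried as boolean masks;
the raw-file convention encodes them as values of 0 or -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

#: Default sampling rate of intrapartum CTG monitors, Hz.
DEFAULT_SAMPLE_RATE = 4.0

#: FHR values outside this range (bpm) are non-physiological; the readers
#: optionally flag them as missing.
PHYSIOLOGICAL_FHR_RANGE = (30.0, 250.0)


class DeliveryMode(str, Enum):
    VAGINAL = "vaginal"
    OPERATIVE = "operative"
    CESAREAN = "cesarean"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CaseMeta:
    """Per-case outcome metadata.

    ``ph`` is the umbilical arterial pH at birth (unitless, plausible range
    6.5-7.6) or ``None`` when unavailable; Apgar scores are integers 0-10.
    """

    ph: float | None = None
    delivery_mode: DeliveryMode = DeliveryMode.UNKNOWN
    apgar1: int | None = None
    apgar5: int | None = None

    def __post_init__(self) -> None:
        if self.ph is not None and not (6.5 <= self.ph <= 7.6):
            raise ValueError(f"pH {self.ph} outside plausible range [6.5, 7.6]")
        for name in ("apgar1", "apgar5"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 10):
                raise ValueError(f"{name}={v} outside [0, 10]")


@dataclass
class CTGRecord:
    """A paired FHR + UC recording on a shared uniform time axis.

    Sample ``k`` occurs ``k / sample_rate`` seconds after record start;
    ``end_offset`` anchors the last sample to delivery (seconds between the
    end of the recording and birth, 0 when unknown).
    """

    case_id: str
    fhr: np.ndarray
    uc: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    end_offset: float = 0.0
    missing_fhr: np.ndarray | None = None
    missing_uc: np.ndarray | None = None
    meta: CaseMeta = field(default_factory=CaseMeta)

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.missing_fhr is None:
            self.missing_fhr = np.zeros(self.fhr.shape, dtype=bool)
        if self.missing_uc is None:
            self.missing_uc = np.zeros(self.uc.shape, dtype=bool)
        self.missing_fhr = np.asarray(self.missing_fhr, dtype=bool)
        self.missing_uc = np.asarray(self.missing_uc, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.fhr.shape != self.uc.shape or self.fhr.ndim != 1:
            raise ValueError("fhr and uc must be 1-D arrays of equal length")
        if self.missing_fhr.shape != self.fhr.shape:
            raise ValueError("missing_fhr mask does not align with fhr")
        if self.missing_uc.shape != self.uc.shape:
            raise ValueError("missing_uc mask does not align with uc")
        if self.end_offset < 0:
            raise ValueError("end_offset must be >= 0")

    def __len__(self) -> int:
        return self.fhr.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate

    def copy(self) -> "CTGRecord":
        return replace(
            self,
            fhr=self.fhr.copy(),
            uc=self.uc.copy(),
            missing_fhr=self.missing_fhr.copy(),
            missing_uc=self.missing_uc.copy(),
        )


@dataclass(frozen=True)
class Segment:
    """A gap-free analysis window cut from a parent record (half-open in
    sample indices).  ``start_before_delivery`` is the time in seconds from
    segment start to delivery."""

    parent_id: str
    start_index: int
    end_index: int
    fhr: np.ndarray
    uc: np.ndarray
    sample_rate: float
    start_before_delivery: float
    meta: CaseMeta = field(default_factory=CaseMeta)

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("empty segment")
        if self.fhr.shape != self.uc.shape:
            raise ValueError("fhr and uc must align")
        if self.fhr.size != self.end_index - self.start_index:
            raise ValueError("series length disagrees with index bounds")

    def __len__(self) -> int:
        return self.fhr.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate


@dataclass(frozen=True)
class Discard:
    """A machine-readable decision that a case cannot be analysed."""

    case_id: str
    reason: str  # "no_window" | "too_early"
    detail: str = ""


class EventKind(str, Enum):
    ACCELERATION = "acceleration"
    DECELERATION = "deceleration"
    CONTRACTION = "contraction"


@dataclass(frozen=True)
class Event:
    """One detected acceleration, deceleration or uterine contraction.

    Intervals are half-open ``[start_s, end_s)`` in seconds from segment
    start.  ``max_depth`` is the peak deviation (bpm for FHR events, mm Hg
    above threshold for contractions); ``area`` integrates the deviation
    over time (bpm*s or mmHg*s).  ``is_late`` marks decelerations lasting
    more than two minutes.
    """

    kind: EventKind
    start_s: float
    end_s: float
    peak_s: float
    max_depth: float
    area: float
    is_late: bool = False

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")
        if not (self.start_s <= self.peak_s < self.end_s):
            raise ValueError("peak_s must lie inside the event interval")
        if self.area < 0:
            raise ValueError("area must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BaselineEstimate:
    """Per-sample FHR baseline with the stability probability that drove it.

    ``p_stab`` is the probability that the trace is in a stable (non-event)
    state; ``half_duration`` is the window half-width T in seconds used at
    each sample (constant in ``fixed`` mode)."""

    baseline: np.ndarray
    p_stab: np.ndarray
    half_duration: np.ndarray
    mode: str  # "fixed" | "variable"

    def __post_init__(self) -> None:
        if not (self.baseline.shape == self.p_stab.shape == self.half_duration.shape):
            raise ValueError("baseline, p_stab and half_duration must align")
        if np.any(self.p_stab < -1e-12) or np.any(self.p_stab > 1 + 1e-12):
            raise ValueError("p_stab must lie in [0, 1]")
        if self.mode not in ("fixed", "variable"):
            raise ValueError("mode must be 'fixed' or 'variable'")


@dataclass(frozen=True)
class FittedModel:
    """A fitted logistic acidosis-risk model.

    Stores the intercept ``beta0`` and coefficients ``beta`` on the
    standardized feature scale, along with the per-feature center/scale
    learned on the training data and the pH cutoff the outcome was defined
    with.  Risk and per-feature contributions are computed by
    :func:`ctglab.model.predict`.
    """

    feature_names: tuple[str, ...]
    beta0: float
    beta: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    outcome_threshold: float = 7.05

    def __post_init__(self) -> None:
        n = len(self.feature_names)
        if not (self.beta.size == self.center.size == self.scale.size == n):
            raise ValueError("coefficient/scaler lengths must match feature_names")
        if np.any(self.scale <= 0):
            raise ValueError("scales must be strictly positive")


def as_float_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    return arr
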