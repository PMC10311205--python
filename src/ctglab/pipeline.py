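"""End-to-end record -> feature-vector pipeline.

Ties together gap interpolation, segment selection, stability scoring,
baseline estimation, event detection and feature computation, so the CLI
and batch evaluations share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess
from .baseline import StabilityModel, estimate_baseline, predict_stability
from .events import detect_accelerations, detect_contractions, detect_decelerations
from .features import FeatureVector, compute_features
from .types import BaselineEstimate, CTGRecord, Discard, Event, Segment


@dataclass
class CaseResult:
    case_id: str
    segment: Segment
    baseline: BaselineEstimate
    accelerations: list[Event]
    decelerations: list[Event]
    contractions: list[Event]
    features: FeatureVector


def analyse_record(
    record: CTGRecord,
    stability_model: StabilityModel | None = None,
    cfg: dict | None = None,
) -> CaseResult | Discard:
    """Run the full analysis on one record.

    With no stability model the baseline degenerates to a plain
    distance-weighted median (p_stab = 1 everywhere).
    """
    from .config import load_config

    cfg = cfg or load_config()
    pp, bl, ev = cfg["preprocess"], cfg["baseline"], cfg["events"]
    rec = preprocess.interpolate_gaps(record, pp["max_gap_s"], pp["interpolation"])
    seg = preprocess.select_segment(rec, pp["segment_len_s"], pp["max_start_before_delivery_s"])
    if isinstance(seg, Discard):
        return seg
    model = stability_model or StabilityModel.constant(1.0)
    p_stab = predict_stability(model, seg.fhr, seg.sample_rate)
    base = estimate_baseline(
        seg.fhr, p_stab, seg.sample_rate,
        mode=bl["mode"], T0=bl["T0_s"], grid_stride=bl["grid_stride"],
        T_clamp=tuple(bl["T_clamp_s"]),
    )
    acc = detect_accelerations(seg.fhr, base.baseline, seg.sample_rate, ev["min_duration_s"])
    dec = detect_decelerations(seg.fhr, base.baseline, seg.sample_rate, ev["min_duration_s"])
    ctr = detect_contractions(
        seg.uc, seg.sample_rate,
        ev["contraction_threshold_mmhg"], ev["contraction_min_duration_s"],
    )
    feats = compute_features(seg, base, acc, dec, ctr)
    return CaseResult(
        case_id=record.case_id, segment=seg, baseline=base,
        accelerations=acc, decelerations=dec, contractions=ctr, features=feats,
    )


def baseline_error(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute baseline error in bpm."""
    return float(np.mean(np.abs(np.asarray(estimated) - np.asarray(truth))))
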