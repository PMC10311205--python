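"""Gap interpolation and analysis-segment selection.

Clinical CTG traces lose signal whenever the transducer slips; the raw
files carry those stretches as in-band missing values.  The pipeline fills
short gaps (< 10 min by default) by interpolation between the valid samples
on either side and then cuts the latest fully gap-free 30-min window for
feature extraction.  Cases with no such window, or whose window starts more
than 90 min before delivery, are discarded rather than analysed.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .types import CTGRecord, Discard, Segment

__all__ = ["interpolate_gaps", "select_segment", "missing_runs"]


def missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``[start, end)`` index ranges of the maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _fill(values: np.ndarray, start: int, end: int, rate: float, method: str) -> np.ndarray:
    """Interpolant across ``[start, end)`` anchored on the samples just
    outside the gap."""
    x0, x1 = start - 1, end  # valid anchors
    xs = np.arange(start, end)
    if method == "linear":
        return np.interp(xs, [x0, x1], [values[x0], values[x1]])
    if method == "cubic_hermite":
        # slopes from one-sided finite differences on the valid side
        d0 = (values[x0] - values[x0 - 1]) * rate if x0 >= 1 else 0.0
        d1 = (values[x1 + 1] - values[x1]) * rate if x1 + 1 < values.size else 0.0
        t = np.array([x0, x1]) / rate
        spline = CubicHermiteSpline(t, values[[x0, x1]], [d0, d1])
        return spline(xs / rate)
    raise ValueError(f"unknown interpolation method {method!r}")


def interpolate_gaps(
    record: CTGRecord,
    max_gap_s: float = 600.0,
    method: str = "linear",
) -> CTGRecord:
    """Fill interior missing runs strictly shorter than ``max_gap_s``.

    Runs touching either record boundary have no anchor on one side and are
    left masked, as are runs of ``max_gap_s`` or longer.  Observed samples
    are never modified.
    """
    out = record.copy()
    for values, mask in ((out.fhr, out.missing_fhr), (out.uc, out.missing_uc)):
        for start, end in missing_runs(mask):
            if start == 0 or end == len(record):
                continue  # boundary gap: no anchor
            if (end - start) / record.sample_rate >= max_gap_s:
                continue
            values[start:end] = _fill(values, start, end, record.sample_rate, method)
            mask[start:end] = False
    return out


def select_segment(
    record: CTGRecord,
    seg_len_s: float = 1800.0,
    max_start_s: float = 5400.0,
) -> Segment | Discard:
    """Latest window of ``seg_len_s`` with no missing FHR or UC sample.

    Windows may start on any sample.  Returns :class:`Discard` with reason
    ``no_window`` when no gap-free window exists, or ``too_early`` when the
    latest one starts more than ``max_start_s`` seconds before delivery
    (delivery time = record end + ``end_offset``).
    """
    n = len(record)
    win = int(round(seg_len_s * record.sample_rate))
    missing = record.missing_fhr | record.missing_uc
    if n < win:
        return Discard(record.case_id, "no_window", f"record shorter than {seg_len_s:g} s")
    # prefix sums: window [s, s+win) is clean iff it contains no missing sample
    csum = np.concatenate(([0], np.cumsum(missing.astype(np.int64))))
    starts = np.arange(n - win + 1)
    clean = (csum[starts + win] - csum[starts]) == 0
    if not clean.any():
        return Discard(record.case_id, "no_window", "no gap-free window")
    start = int(np.flatnonzero(clean)[-1])
    start_before_delivery = record.end_offset + (n - start) / record.sample_rate
    if start_before_delivery > max_start_s:
        return Discard(
            record.case_id,
            "too_early",
            f"window starts {start_before_delivery:.0f} s before delivery (> {max_start_s:g})",
        )
    end = start + win
    return Segment(
        parent_id=record.case_id,
        start_index=start,
        end_index=end,
        fhr=record.fhr[start:end].copy(),
        uc=record.uc[start:end].copy(),
        sample_rate=record.sample_rate,
        start_before_delivery=start_before_delivery,
        meta=record.meta,
    )
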