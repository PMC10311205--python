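"""FHR baseline estimation by a stability-weighted median filter.

The baseline is the slowly varying mean FHR level with accelerations and
decelerations excluded.  Because events are themselves defined relative to
the baseline, the estimator sidesteps the circularity by first scoring each
sample with a probability ``p_stab(t)`` of being in a *stable* (non-event)
state, then taking a weighted median of the FHR in a window around each
time point with weights

    W_t(t') = p_stab(t') * max(0, 1 - |t - t'| / T)

so that event samples (p_stab ~ 0) are excluded and nearby samples count
more.  The half-duration T is either fixed (20 min) or modulated by the
local mean stability, T = 20 min / (3 * mean p_stab on [t-20, t+20] min),
so that unstable stretches get a wider window.

``p_stab`` comes from a logistic model on an 8-variable description of the
local signal dynamics: the absolute first derivatives of the FHR band-pass
filtered in four modulation-frequency bands (0-0.1, 0.1-1, 1-3 and 3-7
cycles/min), and the analytic (Hilbert) envelopes of those derivatives.
High derivatives flag event slopes; high envelopes persist through the
plateau of an event, letting the model separate event troughs from genuine
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateFitError, LengthError
from .types import BaselineEstimate, as_float_array

logger = logging.getLogger(__name__)

#: Modulation-frequency band edges in cycles/min ("bpm" of signal
#: oscillation, not heart beats); 0 means pure low-pass.
DEFAULT_BANDS_BPM: tuple[tuple[float, float], ...] = (
    (0.0, 0.1),
    (0.1, 1.0),
    (1.0, 3.0),
    (3.0, 7.0),
)

FILTER_ORDER = 6
DEFAULT_T0_S = 1200.0  # 20 min half-duration
T_CLAMP_S = (300.0, 3600.0)
DEFAULT_GRID_STRIDE = 4  # evaluate the weighted median every 1 s at 4 Hz


def bandpass(
    fhr: np.ndarray,
    low_bpm: float,
    high_bpm: float,
    sample_rate: float = 4.0,
) -> np.ndarray:
    """Zero-phase 6th-order Butterworth band-pass on modulation frequency.

    Cutoffs are in cycles per minute and converted as ``f_Hz = f_bpm / 60``.
    ``low_bpm = 0`` degenerates to a pure low-pass.
    """
    x = as_float_array(fhr)
    nyq_bpm = sample_rate * 60.0 / 2.0
    if not (0 <= low_bpm < high_bpm < nyq_bpm):
        raise ValueError(
            f"require 0 <= low ({low_bpm}) < high ({high_bpm}) < Nyquist ({nyq_bpm}) cycles/min"
        )
    if x.size <= 3 * FILTER_ORDER:
        raise LengthError(f"series of {x.size} samples too short for order-{FILTER_ORDER} filter")
    if low_bpm == 0:
        sos = butter(FILTER_ORDER, high_bpm / 60.0, btype="lowpass", fs=sample_rate, output="sos")
    else:
        sos = butter(
            FILTER_ORDER,
            [low_bpm / 60.0, high_bpm / 60.0],
            btype="bandpass",
            fs=sample_rate,
            output="sos",
        )
    return sosfiltfilt(sos, x)


def stability_variables(
    fhr: np.ndarray,
    sample_rate: float = 4.0,
    bands_bpm: tuple[tuple[float, float], ...] = DEFAULT_BANDS_BPM,
) -> np.ndarray:
    """The 8 per-sample stability descriptors, shape ``(n, 8)``.

    Columns 0-3: |d(FHR_band)| for the four bands (finite differences, per
    second); columns 4-7: |Hilbert envelope of d(FHR_band)|.
    """
    x = as_float_array(fhr)
    cols = []
    envs = []
    for lo, hi in bands_bpm:
        filt = bandpass(x, lo, hi, sample_rate)
        deriv = np.gradient(filt) * sample_rate
        cols.append(np.abs(deriv))
        envs.append(np.abs(hilbert(deriv)))
    return np.column_stack(cols + envs)


@dataclass(frozen=True)
class StabilityModel:
    """Logistic model mapping the 8 stability variables to p_stab."""

    coef: np.ndarray  # shape (8,), on the standardized variable scale
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    bands_bpm: tuple[tuple[float, float], ...] = DEFAULT_BANDS_BPM

    def __post_init__(self) -> None:
        if self.coef.size != 2 * len(self.bands_bpm):
            raise ValueError("need one coefficient per stability variable")

    @classmethod
    def constant(cls, p: float = 1.0, bands_bpm=DEFAULT_BANDS_BPM) -> "StabilityModel":
        """Degenerate model predicting a constant stability probability
        (``p = 1`` reproduces a plain distance-weighted median filter)."""
        nvar = 2 * len(bands_bpm)
        p = min(max(p, 1e-12), 1 - 1e-12)
        return cls(
            coef=np.zeros(nvar),
            intercept=float(np.log(p / (1 - p))),
            center=np.zeros(nvar),
            scale=np.ones(nvar),
            bands_bpm=tuple(bands_bpm),
        )


def fit_stability_model(
    annotated: list[tuple[np.ndarray, np.ndarray]],
    sample_rate: float = 4.0,
    bands_bpm: tuple[tuple[float, float], ...] = DEFAULT_BANDS_BPM,
    C: float = 1.0,
) -> StabilityModel:
    """Fit the p_stab logistic model on expert-style annotations.

    ``annotated`` holds ``(fhr_series, stable_mask)`` pairs where the mask
    is True outside annotated accelerations/decelerations.  Per-sample
    variables are pooled across recordings, standardized, and fit with a
    lightly L2-regularized logistic regression (keeps separable traces from
    overflowing).
    """
    if len(annotated) < 2:
        raise DegenerateFitError("need at least 2 annotated recordings")
    X = np.vstack([stability_variables(f, sample_rate, bands_bpm) for f, _ in annotated])
    y = np.concatenate([np.asarray(s, dtype=bool) for _, s in annotated])
    if y.all() or not y.any():
        raise DegenerateFitError("stability labels contain a single class")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    clf = LogisticRegression(C=C, max_iter=1000)
    clf.fit(Z, y.astype(int))
    return StabilityModel(
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        center=center,
        scale=scale,
        bands_bpm=tuple(bands_bpm),
    )


def predict_stability(
    model: StabilityModel,
    fhr: np.ndarray,
    sample_rate: float = 4.0,
) -> np.ndarray:
    """Per-sample probability of the stable (non-event) state, in [0, 1]."""
    X = stability_variables(fhr, sample_rate, model.bands_bpm)
    z = (X - model.center) / model.scale
    eta = z @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest value v whose cumulative weight
    (over values <= v) reaches half the total weight."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be aligned 1-D arrays")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("no strictly positive weight")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(v[order[min(idx, v.size - 1)]])


def _lower_wmedian_sorted(v_sorted: np.ndarray, w_in_sorted_order: np.ndarray) -> float:
    cum = np.cumsum(w_in_sorted_order)
    total = cum[-1]
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(v_sorted[min(idx, v_sorted.size - 1)])


def estimate_baseline(
    fhr: np.ndarray,
    p_stab: np.ndarray,
    sample_rate: float = 4.0,
    mode: str = "fixed",
    T0: float = DEFAULT_T0_S,
    grid_stride: int = DEFAULT_GRID_STRIDE,
    T_clamp: tuple[float, float] = T_CLAMP_S,
) -> BaselineEstimate:
    """Stability-weighted median baseline.

    ``fixed`` mode uses the constant half-duration ``T0``; ``variable``
    mode widens the window where the trace is unstable,
    ``T(t) = T0 / (3 * mean p_stab over [t - T0, t + T0])``, clamped to
    ``T_clamp`` to keep the window finite as the local stability tends to
    zero.  Windows truncate at the segment edges.  The median is evaluated
    every ``grid_stride`` samples and linearly interpolated back to the
    full rate (``grid_stride = 1`` reproduces the exact definition).

    A window whose weights sum to zero falls back to the unweighted median
    of the window (logged).
    """
    x = as_float_array(fhr)
    p = as_float_array(p_stab)
    if x.shape != p.shape:
        raise ValueError("fhr and p_stab must align")
    if T0 <= 0:
        raise ValueError("T0 must be positive")
    if mode not in ("fixed", "variable"):
        raise ValueError("mode must be 'fixed' or 'variable'")
    n = x.size
    t = np.arange(n) / sample_rate

    if mode == "variable":
        # running mean of p_stab over [t - T0, t + T0], truncated at edges
        half = int(round(T0 * sample_rate))
        csum = np.concatenate(([0.0], np.cumsum(p)))
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        pbar = (csum[hi] - csum[lo]) / (hi - lo)
        T_all = np.where(pbar > 0, T0 / (3.0 * np.maximum(pbar, 1e-12)), T_clamp[1])
        clamped = (T_all < T_clamp[0]) | (T_all > T_clamp[1])
        if clamped.any():
            logger.debug("variable half-duration clamped at %d samples", int(clamped.sum()))
        # sub-nanosecond float residue in T0 / (3 * pbar) would otherwise
        # admit one spurious edge sample into the window
        T_all = np.round(np.clip(T_all, T_clamp[0], T_clamp[1]), 9)
    else:
        T_all = np.full(n, float(T0))

    grid = np.arange(0, n, max(int(grid_stride), 1))
    # sort once; per grid point the window weight profile is re-laid on the
    # globally sorted values, so each evaluation is O(n) with no re-sort
    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    base_grid = np.empty(grid.size)
    zero_weight = 0
    for j, k in enumerate(grid):
        T = T_all[k]
        half = int(np.ceil(T * sample_rate))
        lo = max(k - half, 0)
        hi = min(k + half + 1, n)
        dist = np.abs(t[lo:hi] - t[k])
        w_win = p[lo:hi] * np.maximum(0.0, 1.0 - dist / T)
        if w_win.sum() <= 0:
            zero_weight += 1
            base_grid[j] = float(np.median(x[lo:hi]))
            continue
        w_full = np.zeros(n)
        w_full[lo:hi] = w_win
        base_grid[j] = _lower_wmedian_sorted(x_sorted, w_full[order])
    if zero_weight:
        logger.warning(
            "%d window(s) had zero total weight; fell back to unweighted median", zero_weight
        )
    baseline = np.interp(np.arange(n), grid, base_grid)
    return BaselineEstimate(
        baseline=baseline,
        p_stab=p,
        half_duration=T_all,
        mode=mode,
    )
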