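"""Synthetic CTG cohorts with full ground truth.

The generator emulates the statistical structure of intrapartum CTG
archives (open CTU-UHB-style recordings and consensus-annotated
FHRMA-style material): 4 Hz paired FHR/UC traces with

* a slowly drifting FHR baseline (band-limited random walk inside a
  plausible 110-160 bpm range),
* Hann-shaped accelerations and decelerations placed by a thinned Poisson
  process (decelerations optionally time-locked to contraction peaks with
  a lag, as seen with cord-compression patterns),
* band-limited variability noise synthesized per modulation band so the
  stability model's recovery problem is well posed,
* bell-shaped uterine contractions over a resting tone, and
* signal-loss gaps written in-band as 0-valued runs.

Every record carries its ground truth: the true baseline, the injected
event intervals, per-sample stable-state labels (stable = outside any
acceleration/deceleration), the true feature vector of the final 30-min
window, and — at cohort level — a pH outcome drawn through a known
logistic link on the four default model features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .baseline import bandpass
from .errors import ParamsError
from .events import detect_accelerations, detect_contractions, detect_decelerations
from .features import DEFAULT_MODEL_FEATURES, FeatureVector, compute_features
from .model import LabeledDataset, weighted_auc
from .types import BaselineEstimate, CaseMeta, CTGRecord, DeliveryMode, Event, Segment


@dataclass(frozen=True)
class SimParams:
    """Generator settings; the defaults are the study conditions."""

    n_cases: int = 100
    duration_s: float = 3600.0
    sample_rate: float = 4.0
    # FHR baseline
    baseline_range_bpm: tuple[float, float] = (110.0, 160.0)
    drift_sd_bpm: float = 8.0
    drift_cutoff_cpm: float = 0.05  # cycles/min; period >= 20 min
    # accelerations / decelerations
    accel_rate_per_h: float = 6.0
    accel_amp_bpm: tuple[float, float] = (15.0, 30.0)
    accel_dur_s: tuple[float, float] = (20.0, 60.0)
    decel_rate_per_h: float = 8.0
    decel_amp_bpm: tuple[float, float] = (20.0, 60.0)
    decel_dur_s: tuple[float, float] = (30.0, 180.0)
    decel_ctr_lock_prob: float = 0.7
    decel_ctr_lag_s: tuple[float, float] = (0.0, 30.0)
    event_margin_s: float = 10.0  # minimum spacing between FHR events
    # variability noise per band, cycles/min edges : target sd in bpm
    variability_bands_cpm: tuple[tuple[float, float], ...] = ((0.1, 1.0), (1.0, 3.0), (3.0, 7.0))
    variability_sd_bpm: tuple[float, ...] = (2.0, 1.5, 1.0)
    # uterine activity
    ctr_period_s: tuple[float, float] = (120.0, 300.0)
    ctr_dur_s: tuple[float, float] = (60.0, 100.0)
    ctr_peak_mmhg: tuple[float, float] = (30.0, 80.0)
    uc_tone_mmhg: float = 5.0
    uc_noise_sd_mmhg: float = 1.0
    # signal loss
    gap_rate_per_h: float = 4.0
    gap_dur_s: tuple[float, float] = (5.0, 120.0)
    # outcome link on standardized (b_min, b_max, acc_area, dec_area)
    outcome_beta: tuple[float, ...] = (-0.8, 0.8, 0.5, 1.0)
    outcome_features: tuple[str, ...] = DEFAULT_MODEL_FEATURES
    prevalence: float = 0.10
    outcome_threshold_ph: float = 7.05
    feature_window_s: float = 1800.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "baseline_range_bpm", "accel_amp_bpm", "accel_dur_s", "decel_amp_bpm",
            "decel_dur_s", "decel_ctr_lag_s", "ctr_period_s", "ctr_dur_s",
            "ctr_peak_mmhg", "gap_dur_s",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParamsError(f"{name} range is not ordered: {(lo, hi)}")
        for name in ("accel_rate_per_h", "decel_rate_per_h", "gap_rate_per_h"):
            if getattr(self, name) < 0:
                raise ParamsError(f"{name} must be >= 0")
        if not (0 < self.prevalence < 1):
            raise ParamsError("prevalence must be in (0, 1)")
        if len(self.outcome_beta) != len(self.outcome_features):
            raise ParamsError("outcome_beta must match outcome_features")
        # expected fraction of time inside FHR events must leave room for
        # the rejection sampler to place them without overlap
        occ = (
            self.accel_rate_per_h * np.mean(self.accel_dur_s)
            + self.decel_rate_per_h * np.mean(self.decel_dur_s)
        ) / 3600.0
        if occ > 0.6:
            raise ParamsError(
                f"expected event occupancy {occ:.0%} > 60%: events cannot avoid overlapping"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows about one record."""

    case_id: str
    baseline: np.ndarray  # true FHR baseline, full record, 4 Hz
    accel_intervals: list[tuple[float, float]]
    decel_intervals: list[tuple[float, float]]
    ctr_intervals: list[tuple[float, float]]
    stable: np.ndarray  # per-sample bool, True outside accel/decel
    features: FeatureVector  # true features of the final analysis window
    true_events: dict[str, list[Event]] = field(default_factory=dict)
    outcome_p: float | None = None
    outcome: bool | None = None


def _hann_bump(n: int, t: np.ndarray, start_s: float, dur_s: float, amp: float) -> np.ndarray:
    out = np.zeros(n)
    inside = (t >= start_s) & (t < start_s + dur_s)
    phase = (t[inside] - start_s) / dur_s
    out[inside] = amp * np.sin(np.pi * phase) ** 2
    return out


def _band_noise(n: int, rng: np.random.Generator, band_cpm: tuple[float, float],
                sd: float, fs: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    filt = bandpass(white, band_cpm[0], band_cpm[1], fs)
    s = filt.std()
    return filt * (sd / s) if s > 0 else np.zeros(n)


def _place_events(
    rng: np.random.Generator,
    rate_per_h: float,
    dur_range: tuple[float, float],
    duration_s: float,
    occupied: list[tuple[float, float]],
    margin_s: float,
    max_tries: int = 200,
) -> list[tuple[float, float]]:
    """Thinned Poisson placement with overlap rejection.

    An event that cannot be placed after ``max_tries`` draws is dropped
    (thinning); genuinely infeasible rates are rejected up front by
    :meth:`SimParams.validate`.
    """
    n_events = rng.poisson(rate_per_h * duration_s / 3600.0)
    placed = []
    for _ in range(n_events):
        for _try in range(max_tries):
            dur = rng.uniform(*dur_range)
            start = rng.uniform(0.0, max(duration_s - dur, 1e-9))
            iv = (start, start + dur)
            if all(iv[1] + margin_s <= a or iv[0] >= b + margin_s for a, b in occupied):
                occupied.append(iv)
                placed.append(iv)
                break
    return placed


def simulate_record(params: SimParams, case_seed: int, case_id: str | None = None
                    ) -> tuple[CTGRecord, GroundTruth]:
    """Generate one record and its ground truth.

    Ground truth (true baseline, events, features, stability labels) is
    recorded before gap insertion; gaps only overwrite the in-band values.
    """
    params.validate()
    rng = np.random.default_rng(case_seed)
    fs = params.sample_rate
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    # --- true baseline: level + band-limited drift, reflected into range
    lo, hi = params.baseline_range_bpm
    level = rng.uniform(lo + 10, hi - 10)
    drift = _band_noise(n, rng, (0.0, params.drift_cutoff_cpm), params.drift_sd_bpm, fs) \
        if params.drift_sd_bpm > 0 else np.zeros(n)
    true_baseline = np.clip(level + drift, lo, hi)

    # --- uterine activity
    uc = np.full(n, params.uc_tone_mmhg)
    ctr_peak_times: list[float] = []
    ctr_intervals: list[tuple[float, float]] = []
    tt = rng.uniform(0, params.ctr_period_s[0])
    while tt < params.duration_s:
        dur = rng.uniform(*params.ctr_dur_s)
        peak = rng.uniform(*params.ctr_peak_mmhg)
        start = tt - dur / 2.0
        uc += _hann_bump(n, t, start, dur, peak - params.uc_tone_mmhg)
        ctr_peak_times.append(tt)
        ctr_intervals.append((max(start, 0.0), min(start + dur, params.duration_s)))
        tt += rng.uniform(*params.ctr_period_s)
    uc_clean = uc.copy()
    if params.uc_noise_sd_mmhg > 0:
        uc = uc + _band_noise(n, rng, (0.0, 2.0), params.uc_noise_sd_mmhg, fs)
    uc = np.clip(uc, 0.5, None)

    # --- FHR events
    occupied: list[tuple[float, float]] = []
    accel_iv = _place_events(rng, params.accel_rate_per_h, params.accel_dur_s,
                             params.duration_s, occupied, params.event_margin_s)
    # decelerations: a fraction is re-centred on a contraction peak + lag
    decel_iv = _place_events(rng, params.decel_rate_per_h, params.decel_dur_s,
                             params.duration_s, occupied, params.event_margin_s)
    if ctr_peak_times and params.decel_ctr_lock_prob > 0:
        locked = []
        for (start, end) in decel_iv:
            dur = end - start
            if rng.uniform() < params.decel_ctr_lock_prob:
                peak_t = ctr_peak_times[int(np.argmin(np.abs(np.asarray(ctr_peak_times) - start)))]
                lag = rng.uniform(*params.decel_ctr_lag_s)
                c = min(max(peak_t + lag, dur / 2), params.duration_s - dur / 2)
                cand = (c - dur / 2, c + dur / 2)
                others = [iv for iv in occupied if iv != (start, end)]
                if all(cand[1] + params.event_margin_s <= a or cand[0] >= b + params.event_margin_s
                       for a, b in others):
                    occupied.remove((start, end))
                    occupied.append(cand)
                    locked.append(cand)
                    continue
            locked.append((start, end))
        decel_iv = locked

    deviation = np.zeros(n)
    for (start, end) in accel_iv:
        amp = rng.uniform(*params.accel_amp_bpm)
        deviation += _hann_bump(n, t, start, end - start, amp)
    for (start, end) in decel_iv:
        amp = rng.uniform(*params.decel_amp_bpm)
        deviation -= _hann_bump(n, t, start, end - start, amp)

    noise = np.zeros(n)
    for band, sd in zip(params.variability_bands_cpm, params.variability_sd_bpm):
        noise += _band_noise(n, rng, band, sd, fs)

    fhr_clean = true_baseline + deviation  # noise-free rendering
    fhr = fhr_clean + noise

    # --- stability labels: stable <=> outside every accel/decel interval
    stable = np.ones(n, dtype=bool)
    for (start, end) in accel_iv + decel_iv:
        stable[(t >= start) & (t < end)] = False

    # --- true features of the final analysis window
    w = int(round(params.feature_window_s * fs))
    w = min(w, n)
    sl = slice(n - w, n)
    off = t[sl.start]
    seg = Segment(
        parent_id=case_id or f"sim{case_seed}",
        start_index=sl.start, end_index=n,
        fhr=fhr[sl], uc=uc[sl], sample_rate=fs,
        start_before_delivery=params.feature_window_s,
    )
    true_base = BaselineEstimate(
        baseline=true_baseline[sl],
        p_stab=stable[sl].astype(float),
        half_duration=np.zeros(w),
        mode="fixed",
    )
    # event truth from the noise-free rendering against the true baseline
    accel_ev = detect_accelerations(fhr_clean[sl], true_baseline[sl], fs)
    decel_ev = detect_decelerations(fhr_clean[sl], true_baseline[sl], fs)
    ctr_ev = detect_contractions(uc_clean[sl], fs)
    features = compute_features(seg, true_base, accel_ev, decel_ev, ctr_ev)

    # --- gaps (after truth capture)
    missing = np.zeros(n, dtype=bool)
    n_gaps = rng.poisson(params.gap_rate_per_h * params.duration_s / 3600.0)
    for _ in range(n_gaps):
        dur = rng.uniform(*params.gap_dur_s)
        start = rng.uniform(0, max(params.duration_s - dur, 1e-9))
        missing[(t >= start) & (t < start + dur)] = True
    fhr_out = fhr.copy()
    uc_out = uc.copy()
    fhr_out[missing] = 0.0
    uc_out[missing] = 0.0

    cid = case_id or f"sim{case_seed}"
    record = CTGRecord(
        case_id=cid,
        fhr=fhr_out,
        uc=uc_out,
        sample_rate=fs,
        end_offset=0.0,
        missing_fhr=missing.copy(),
        missing_uc=missing.copy(),
    )
    truth = GroundTruth(
        case_id=cid,
        baseline=true_baseline,
        accel_intervals=accel_iv,
        decel_intervals=decel_iv,
        ctr_intervals=ctr_intervals,
        stable=stable,
        features=features,
        true_events={"acceleration": accel_ev, "deceleration": decel_ev,
                     "contraction": ctr_ev},
    )
    return record, truth


def _tune_intercept(eta_no_icpt: np.ndarray, target: float) -> float:
    """Bisection on beta0 so the mean simulated risk hits the target
    prevalence."""
    lo, hi = -30.0, 30.0

    def prev(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_no_icpt)))))

    if not (prev(lo) <= target <= prev(hi)):
        raise ParamsError(f"prevalence {target} unattainable with the given link")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    params: SimParams,
    keep_records: bool = False,
) -> tuple[LabeledDataset, list[GroundTruth], list[CTGRecord] | None]:
    """Generate a labelled cohort.

    Outcomes are Bernoulli draws from ``logistic(beta0 + beta . z)`` where
    ``z`` are the true features standardized over the cohort, and ``beta0``
    is tuned by bisection so the mean risk equals the target prevalence.
    The drawn label determines the recorded pH (below / above the cutoff).
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(params.n_cases)]
    rng = np.random.default_rng(root.spawn(1)[0])

    records: list[CTGRecord] = []
    truths: list[GroundTruth] = []
    for i, cs in enumerate(case_seeds):
        rec, tr = simulate_record(params, cs, case_id=f"case{i:05d}")
        truths.append(tr)
        if keep_records:
            records.append(rec)
    X = np.vstack([tr.features.as_array(params.outcome_features) for tr in truths])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    eta = ((X - mu) / sd) @ np.asarray(params.outcome_beta)
    beta0 = _tune_intercept(eta, params.prevalence)
    p = 1.0 / (1.0 + np.exp(-(beta0 + eta)))
    y = rng.uniform(size=params.n_cases) < p

    thr = params.outcome_threshold_ph
    case_ids, metas = [], []
    for i, tr in enumerate(truths):
        tr.outcome_p = float(p[i])
        tr.outcome = bool(y[i])
        ph = rng.uniform(6.85, thr - 0.01) if y[i] else rng.uniform(thr + 0.01, 7.40)
        mode = DeliveryMode(rng.choice(["vaginal", "operative", "cesarean"], p=[0.7, 0.15, 0.15]))
        metas.append(CaseMeta(ph=float(ph), delivery_mode=mode))
        case_ids.append(tr.case_id)
        if keep_records:
            records[i] = replace(records[i], meta=metas[-1])

    dataset = LabeledDataset(
        case_ids=case_ids,
        features=[tr.features for tr in truths],
        outcomes=y,
        centers=["sim"] * params.n_cases,
        outcome_threshold=thr,
    )
    return dataset, truths, (records if keep_records else None)


def cohort_bayes_auc(truths: list[GroundTruth]) -> float:
    """Bayes-optimal AUC of the generator's own risk probabilities,
    computed on the simulated feature sample (soft-label Mann-Whitney)."""
    p = np.array([tr.outcome_p for tr in truths], dtype=float)
    return weighted_auc(p, p, 1.0 - p)


def simulate_annotated_set(
    params: SimParams,
    n_records: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Consensus-annotation-style material: ``(fhr, stable_labels,
    true_baseline)`` per record, gap-free, for calibrating the stability
    model and scoring baseline error against a known truth."""
    params = replace(params, gap_rate_per_h=0.0,
                     n_cases=n_records or params.n_cases)
    root = np.random.SeedSequence((params.seed, 77))
    out = []
    for i, s in enumerate(root.spawn(params.n_cases)):
        rec, tr = simulate_record(params, int(s.generate_state(1)[0] % (2**31)),
                                  case_id=f"ann{i:03d}")
        out.append((rec.fhr, tr.stable, tr.baseline))
    return out


def simulate_event_benchmark(
    params: SimParams,
    n_segments: int = 200,
    seed: int = 0,
    margin: float = 0.2,
) -> list[tuple[CTGRecord, GroundTruth]]:
    """Segments whose injected events meet the detection criteria with at
    least the given relative margin (amplitudes and durations pushed away
    from the thresholds, variability turned down) so detector sensitivity
    and false-discovery rate can be measured against an exact truth."""
    amp_floor = 2 * 10.0 * (1 + margin)  # mean-deviation rule: Hann mean = amp/2
    p = replace(
        params,
        duration_s=params.feature_window_s,
        accel_amp_bpm=(max(amp_floor, params.accel_amp_bpm[0]),
                       max(amp_floor + 6, params.accel_amp_bpm[1])),
        decel_amp_bpm=(max(amp_floor, params.decel_amp_bpm[0]),
                       max(amp_floor + 6, params.decel_amp_bpm[1])),
        accel_dur_s=(max(15.0 * (1 + margin), params.accel_dur_s[0]), params.accel_dur_s[1]),
        decel_dur_s=(max(15.0 * (1 + margin), params.decel_dur_s[0]), params.decel_dur_s[1]),
        # no FHR variability noise: against the flat true baseline, any
        # one-signed noise stretch extends a candidate run beyond the
        # injected bump and dilutes its mean deviation below the criterion,
        # so noisy bumps cannot be guaranteed to meet the criteria with
        # margin.  The benchmark isolates criterion fidelity; noise
        # robustness is exercised by the full-pipeline cohort tests.
        variability_sd_bpm=tuple(0.0 for _ in params.variability_sd_bpm),
        uc_noise_sd_mmhg=0.3,
        gap_rate_per_h=0.0,
        drift_sd_bpm=2.0,
    )
    root = np.random.SeedSequence((seed, 911))
    return [
        simulate_record(p, int(s.generate_state(1)[0] % (2**31)), case_id=f"bench{i:03d}")
        for i, s in enumerate(root.spawn(n_segments))
    ]
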