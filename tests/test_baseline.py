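"""Filter bank, stability model, weighted median and baseline estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctglab.baseline import (
    StabilityModel,
    bandpass,
    estimate_baseline,
    fit_stability_model,
    predict_stability,
    stability_variables,
    weighted_median,
)
from ctglab.errors import DegenerateFitError, LengthError
from ctglab.model import auc

FS = 4.0


def brute_force_weighted_median(values, weights):
    """O(n^2) oracle: smallest v with cumulative weight(<= v) >= total/2."""
    total = sum(weights)
    best = None
    for v in sorted(values):
        cum = sum(w for x, w in zip(values, weights) if x <= v)
        if cum >= total / 2:
            best = v
            break
    return best


# --------------------------------------------------------------------- bandpass

def test_bandpass_zero_in_zero_out():
    out = bandpass(np.zeros(5000), 0.1, 1.0, FS)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_bandpass_passband_gain_near_unity():
    # 0.5 cycles/min sine through the 0.1-1 cycles/min band
    t = np.arange(0, 3 * 3600, 1 / FS)
    x = np.sin(2 * np.pi * (0.5 / 60.0) * t)
    y = bandpass(x, 0.1, 1.0, FS)
    mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
    gain = np.abs(y[mid]).max()
    assert 0.7 <= gain <= 1.02  # small headroom for filtfilt ripple


def test_bandpass_stopband_attenuation():
    t = np.arange(0, 3600, 1 / FS)
    x = np.sin(2 * np.pi * (30.0 / 60.0) * t)  # 30 cycles/min
    y = bandpass(x, 0.0, 0.1, FS)  # low-pass at 0.1 cycles/min
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    assert np.abs(y[mid]).max() < 0.01


def test_bandpass_rejects_short_series_and_bad_edges():
    with pytest.raises(LengthError):
        bandpass(np.zeros(10), 0.1, 1.0, FS)
    with pytest.raises(ValueError):
        bandpass(np.zeros(100), 1.0, 0.5, FS)
    with pytest.raises(ValueError):
        bandpass(np.zeros(100), 0.0, 130.0, FS)  # above Nyquist (120 cpm)


# ---------------------------------------------------------- stability variables

def test_stability_variables_constant_signal_near_zero():
    X = stability_variables(np.full(4000, 142.0), FS)
    assert X.shape == (4000, 8)
    assert np.all(X < 1e-6)
    assert np.all(X >= 0)


def test_stability_variables_bump_peaks_inside_event():
    # 20-bpm, 30-s Hann bump on a flat trace: the 1-3 cycles/min channel
    # (index 2) must peak inside the bump interval
    n = int(1800 * FS)
    t = np.arange(n) / FS
    x = np.full(n, 140.0)
    inside = (t >= 900) & (t < 930)
    x[inside] += 20 * np.sin(np.pi * (t[inside] - 900) / 30) ** 2
    X = stability_variables(x, FS)
    k = int(np.argmax(X[:, 2]))
    assert 900 * FS <= k < 930 * FS


def test_envelope_dominates_derivative(one_record):
    _, record, _ = one_record
    X = stability_variables(record.fhr[: int(1800 * FS)], FS)
    for band in range(4):
        frac = np.mean(X[:, 4 + band] >= X[:, band] - 1e-9)
        assert frac >= 0.99


# ------------------------------------------------------------- stability model

def _two_class_toy(rng, n=4000):
    x = np.full(n, 140.0)
    stable = np.ones(n, dtype=bool)
    for s in range(400, n - 400, 800):
        t = np.arange(200) / FS
        x[s : s + 200] += 25 * np.sin(np.pi * t / 50.0) ** 2
        stable[s : s + 200] = False
    x += 0.5 * rng.standard_normal(n)
    return x, stable


def test_fit_requires_two_recordings_and_two_classes(rng):
    x, stable = _two_class_toy(rng)
    with pytest.raises(DegenerateFitError):
        fit_stability_model([(x, stable)])
    with pytest.raises(DegenerateFitError):
        fit_stability_model([(x, np.ones_like(stable)), (x, np.ones_like(stable))])


def test_fit_on_separable_data_converges_with_high_training_auc(rng):
    x1, s1 = _two_class_toy(rng)
    x2, s2 = _two_class_toy(rng)
    model = fit_stability_model([(x1, s1), (x2, s2)])
    p = predict_stability(model, x1, FS)
    assert np.all((0 <= p) & (p <= 1))
    assert auc(p, s1) > 0.99


def test_stability_parameter_recovery_from_known_logistic_rule(rng):
    # labels drawn from a known logistic rule on the 8 variables
    true_beta = np.array([-1.2, -0.8, -2.0, -1.0, -0.5, -1.5, -2.5, -0.7])
    recs = []
    for _ in range(6):
        x, _ = _two_class_toy(rng)
        X = stability_variables(x, FS)
        z = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        eta = 2.0 + z @ true_beta
        y = rng.uniform(size=len(x)) < 1 / (1 + np.exp(-eta))
        recs.append((x, y))
    model = fit_stability_model(recs, FS, C=10.0)
    rel = np.abs(model.coef - true_beta) / np.abs(true_beta)
    assert np.median(rel) < 0.10  # well-identified variables recover closely


def test_predict_stability_zero_model_gives_half(one_record):
    _, record, _ = one_record
    m = StabilityModel(coef=np.zeros(8), intercept=0.0,
                       center=np.zeros(8), scale=np.ones(8))
    p = predict_stability(m, record.fhr[:4000], FS)
    assert p.shape == (4000,)
    np.testing.assert_allclose(p, 0.5)


def test_pstab_lower_inside_events_than_outside(one_record):
    params, record, truth = one_record
    from ctglab.synthetic import simulate_annotated_set

    ann = simulate_annotated_set(params, 4)
    model = fit_stability_model([(f, s) for f, s, _ in ann[:3]])
    f, s, _ = ann[3]
    p = predict_stability(model, f, FS)
    assert p[~s].mean() < p[s].mean()


# ------------------------------------------------------------- weighted median

@pytest.mark.parametrize(
    "values,weights,expected",
    [
        ([1, 2, 3], [1, 1, 1], 2),
        ([0, 10], [3, 1], 0),
        ([140, 140, 140], [0.2, 5, 1], 140),
        ([5, 1], [1, 1], 1),  # lower median on even total
    ],
)
def test_weighted_median_examples(values, weights, expected):
    assert weighted_median(np.array(values, float), np.array(weights, float)) == expected


def test_weighted_median_rejects_zero_support():
    with pytest.raises(ValueError):
        weighted_median(np.array([1.0, 2.0]), np.array([0.0, 0.0]))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.data())
def test_weighted_median_matches_brute_force(data):
    n = data.draw(st.integers(1, 30))
    values = data.draw(
        st.lists(st.integers(-50, 50), min_size=n, max_size=n)
    )
    weights = data.draw(
        st.lists(st.integers(0, 10), min_size=n, max_size=n)
    )
    if sum(weights) == 0:
        weights[0] = 1
    got = weighted_median(np.array(values, float), np.array(weights, float))
    assert got == brute_force_weighted_median(values, weights)


# ----------------------------------------------------------- baseline estimate

def test_constant_signal_constant_baseline():
    x = np.full(int(1800 * FS), 140.0)
    for mode in ("fixed", "variable"):
        est = estimate_baseline(x, np.ones_like(x), FS, mode=mode)
        np.testing.assert_allclose(est.baseline, 140.0)


def test_variable_mode_equals_fixed_when_mean_pstab_is_one_third(rng):
    x = 140 + 5 * rng.standard_normal(int(1800 * FS))
    p = np.full_like(x, 1 / 3)
    fixed = estimate_baseline(x, p, FS, mode="fixed", T0=1200.0)
    variable = estimate_baseline(x, p, FS, mode="variable", T0=1200.0)
    np.testing.assert_allclose(variable.baseline, fixed.baseline)
    np.testing.assert_allclose(variable.half_duration, 1200.0)


def test_zero_pstab_region_excluded_from_baseline():
    # a 25-bpm, 60-s bump with p_stab = 0 inside must barely move the baseline
    n = int(1800 * FS)
    t = np.arange(n) / FS
    x = np.full(n, 140.0)
    inside = (t >= 870) & (t < 930)
    x[inside] += 25 * np.sin(np.pi * (t[inside] - 870) / 60) ** 2
    p = np.ones(n)
    p[inside] = 0.0
    est = estimate_baseline(x, p, FS, mode="fixed")
    assert np.abs(est.baseline - 140.0).max() < 1.0


def test_zero_total_weight_falls_back_to_unweighted_median(caplog):
    x = np.linspace(130, 150, 800)
    p = np.zeros_like(x)
    est = estimate_baseline(x, p, FS, mode="fixed", T0=10.0)
    assert np.all((x.min() <= est.baseline) & (est.baseline <= x.max()))


def test_baseline_shift_equivariance(rng):
    x = 140 + 6 * rng.standard_normal(int(900 * FS))
    p = rng.uniform(0.2, 1.0, size=x.size)
    a = estimate_baseline(x, p, FS, mode="fixed", T0=300.0)
    b = estimate_baseline(x + 13.5, p, FS, mode="fixed", T0=300.0)
    np.testing.assert_allclose(b.baseline - a.baseline, 13.5, atol=1e-9)


def test_pstab_one_reduces_to_distance_weighted_median(rng):
    # stride=1 must reproduce the direct per-sample definition elementwise
    x = 140 + 8 * rng.standard_normal(240)
    T0 = 20.0
    est = estimate_baseline(x, np.ones_like(x), FS, mode="fixed", T0=T0, grid_stride=1)
    t = np.arange(x.size) / FS
    for k in range(0, x.size, 17):
        w = np.maximum(0.0, 1.0 - np.abs(t - t[k]) / T0)
        expected = brute_force_weighted_median(list(x), list(w))
        assert est.baseline[k] == pytest.approx(expected)


def test_baseline_bounded_by_positive_weight_samples(rng):
    x = 140 + 10 * rng.standard_normal(int(600 * FS))
    p = rng.uniform(0.0, 1.0, size=x.size)
    est = estimate_baseline(x, p, FS, mode="fixed", T0=120.0, grid_stride=1)
    assert np.all(est.baseline >= x.min()) and np.all(est.baseline <= x.max())
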