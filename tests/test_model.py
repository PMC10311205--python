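"""Class-balanced logistic model, AUC, CV protocols and contributions."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ctglab.errors import DegenerateFitError, UndefinedMetricError
from ctglab.features import FEATURE_NAMES, FeatureVector
from ctglab.model import (
    LabeledDataset,
    auc,
    balanced_weights,
    cross_center_eval,
    decision_terms,
    fit,
    kfold_eval,
    predict,
    predict_scores,
    weighted_auc,
)
from ctglab.types import FittedModel


def make_fv(b_min=130.0, b_max=150.0, acc_area=500.0, dec_area=1000.0, **kw):
    vals = dict.fromkeys(FEATURE_NAMES, 0.0)
    vals.update(b_min=b_min, b_med=(b_min + b_max) / 2, b_max=b_max,
                acc_area=acc_area, dec_area=dec_area)
    vals.update(kw)
    return FeatureVector(**vals)


def make_dataset(rng, n=400, beta=(-0.8, 0.8, 0.5, 1.0), b0=-2.0, centers=None):
    Z = rng.standard_normal((n, 4))
    eta = b0 + Z @ np.asarray(beta)
    y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
    fvs = [make_fv(b_min=130 + z[0], b_max=150 + z[1],
                   acc_area=500 + 100 * z[2], dec_area=1000 + 100 * z[3])
           for z in Z]
    return LabeledDataset(
        case_ids=[f"c{i}" for i in range(n)],
        features=fvs,
        outcomes=y,
        centers=list(centers) if centers is not None else [],
    )


# ------------------------------------------------------------------ weighting

def test_balanced_weights_equalize_class_totals():
    y = np.array([True] * 10 + [False] * 90)
    w = balanced_weights(y)
    assert w[y].sum() == pytest.approx(w[~y].sum())
    assert w[y][0] / w[~y][0] == pytest.approx(9.0)  # each pathological weighs 9x


def test_fit_rejects_single_class(rng):
    ds = make_dataset(rng, 50)
    ds.outcomes[:] = False
    with pytest.raises(DegenerateFitError):
        fit(ds)


def test_fit_rejects_unknown_feature(rng):
    with pytest.raises(KeyError):
        fit(make_dataset(rng, 60), feature_subset=("b_min", "not_a_feature"))


def test_duplication_and_weight_halving_leave_fit_unchanged(rng):
    # duplicating every pathological case while halving its weight is a
    # no-op: the weighted losses are identical functions of the raw-scale
    # coefficients (the stored scalers differ, so compare on the raw scale)
    ds = make_dataset(rng, 300)
    w = balanced_weights(ds.outcomes)
    m1 = fit(ds, sample_weight=w)
    pos = np.flatnonzero(ds.outcomes)
    idx = np.concatenate([np.arange(len(ds)), pos])
    ds2 = ds.subset(idx)
    w2 = np.concatenate([w, w[pos]])
    w2[np.concatenate([pos, np.arange(len(ds), len(ds) + pos.size)])] /= 2.0
    m2 = fit(ds2, sample_weight=w2)
    np.testing.assert_allclose(m1.beta / m1.scale, m2.beta / m2.scale, atol=1e-6)
    np.testing.assert_allclose(predict_scores(m1, ds), predict_scores(m2, ds), atol=1e-6)


# ---------------------------------------------------------------- predictions

def _toy_model(beta, names=None):
    k = len(beta)
    names = names or tuple(f"f{i}" for i in range(k))
    # center 0 / scale 1 so raw features are the standardized ones
    return FittedModel(names, 0.0, np.asarray(beta, float), np.zeros(k), np.ones(k))


def test_risk_is_half_when_linear_predictor_is_zero():
    m = _toy_model([1.0, -2.0])
    p = predict(m, {"f0": 0.0, "f1": 0.0})
    assert p.risk == pytest.approx(0.5)


def test_signed_contributions_split_equally_for_equal_terms():
    m = _toy_model([2.0, 2.0])
    p = predict(m, {"f0": 1.0, "f1": 1.0}, variant="signed")
    assert p.contributions == pytest.approx({"f0": 0.5, "f1": 0.5})


def test_positive_only_contributions_drop_negative_terms():
    m = _toy_model([3.0, -1.0, 1.0])
    p = predict(m, {"f0": 1.0, "f1": 1.0, "f2": 1.0}, variant="positive_only")
    assert p.contributions == pytest.approx({"f0": 0.75, "f1": 0.0, "f2": 0.25})


def test_predict_missing_feature_raises():
    m = _toy_model([1.0, 1.0])
    with pytest.raises(KeyError):
        predict(m, {"f0": 1.0})


def test_risk_strictly_increasing_in_positive_coefficient_feature():
    m = _toy_model([0.7, -0.3])
    risks = [predict(m, {"f0": v, "f1": 0.2}).risk for v in np.linspace(-3, 3, 11)]
    assert np.all(np.diff(risks) > 0)


def test_decision_terms_use_stored_scaler():
    m = FittedModel(("a",), 0.0, np.array([2.0]), np.array([10.0]), np.array([5.0]))
    np.testing.assert_allclose(decision_terms(m, {"a": 20.0}), [2.0 * (20 - 10) / 5])


# ------------------------------------------------------------------------ AUC

def test_auc_perfect_ranking():
    assert auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0


def test_auc_random_scores_near_half(rng):
    n = 10000
    s = rng.uniform(size=n)
    y = rng.uniform(size=n) < 0.3
    assert auc(s, y) == pytest.approx(0.5, abs=0.02)


def test_auc_matches_sklearn_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(10, 80))
        s = rng.integers(0, 10, size=n).astype(float)  # many ties
        y = rng.uniform(size=n) < 0.4
        if y.all() or not y.any():
            continue
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s))


def test_auc_invariant_under_monotone_transform(rng):
    s = rng.standard_normal(500)
    y = rng.uniform(size=500) < 0.2
    a = auc(s, y)
    assert auc(np.exp(s), y) == pytest.approx(a)
    assert auc(2 * s + 7, y) == pytest.approx(a)


def test_auc_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        auc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_weighted_auc_reduces_to_auc_for_hard_labels(rng):
    s = rng.standard_normal(300)
    y = rng.uniform(size=300) < 0.3
    assert weighted_auc(s, y.astype(float), 1.0 - y) == pytest.approx(auc(s, y))


# -------------------------------------------------------------------- k-fold

def test_kfold_deterministic_given_seed(rng):
    ds = make_dataset(rng, 200)
    a = kfold_eval(ds, k=5, seed=11)
    b = kfold_eval(ds, k=5, seed=11)
    np.testing.assert_array_equal(a["folds"], b["folds"])
    assert a["fold_aucs"] == b["fold_aucs"]
    assert a["pooled_auc"] == b["pooled_auc"]


def test_kfold_rejects_k_above_minority_count(rng):
    ds = make_dataset(rng, 40)
    ds.outcomes[:] = False
    ds.outcomes[:3] = True
    with pytest.raises(DegenerateFitError):
        kfold_eval(ds, k=5, seed=0)


def test_kfold_recovers_generator_auc(rng):
    # direct feature simulation with a known link: pooled CV AUC close to
    # the Bayes AUC computed from the true probabilities
    n = 4000
    beta = np.array([-0.8, 0.8, 0.5, 1.0])
    Z = rng.standard_normal((n, 4))
    eta = -2.2 + Z @ beta
    p = 1 / (1 + np.exp(-eta))
    y = rng.uniform(size=n) < p
    fvs = [make_fv(b_min=130 + z[0], b_max=150 + z[1],
                   acc_area=500 + 100 * z[2], dec_area=1000 + 100 * z[3]) for z in Z]
    ds = LabeledDataset([f"c{i}" for i in range(n)], fvs, y)
    bayes = weighted_auc(p, p, 1 - p)
    res = kfold_eval(ds, k=5, seed=3)
    assert res["pooled_auc"] == pytest.approx(bayes, abs=0.04)


# ------------------------------------------------------------- cross-center

def test_cross_center_exchangeable_centers_similar_auc(rng):
    centers = ["A"] * 400 + ["B"] * 400 + ["C"] * 400
    ds = make_dataset(rng, 1200, centers=centers)
    res = cross_center_eval(ds)
    assert set(res) == {"A", "B", "C"}
    vals = np.array(list(res.values()))
    assert vals.max() - vals.min() < 0.12  # within sampling error


def test_cross_center_requires_two_centers(rng):
    ds = make_dataset(rng, 100, centers=["A"] * 100)
    with pytest.raises(DegenerateFitError):
        cross_center_eval(ds)


def test_cross_center_single_class_center(rng):
    # center B is all-normal: its held-out AUC is undefined; the other
    # centers still train on mixed data
    centers = ["A"] * 200 + ["B"] * 50 + ["C"] * 200
    ds = make_dataset(rng, 450, centers=centers)
    ds.outcomes[200:250] = False
    assert ds.outcomes[:200].any() and ds.outcomes[250:].any()
    with pytest.raises(UndefinedMetricError):
        cross_center_eval(ds)
    res = cross_center_eval(ds, skip_undefined=True)
    assert np.isnan(res["B"]) and np.isfinite(res["A"]) and np.isfinite(res["C"])
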