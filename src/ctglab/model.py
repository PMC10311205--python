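"""Class-balanced logistic model of fetal acidosis risk.

The outcome is binary: umbilical arterial pH below a cutoff (7.05 by
default).  Because acidosis is rare, each case is weighted ``N / (2 *
N_class)`` so normal and pathological cases carry equal total weight.
Features are standardized from the training data before the fit; the
stored center/scale makes predictions and contributions reproducible on
new cases.

The fitted risk is ``p = logistic(beta0 + sum_i beta_i x_i)`` on the
standardized features, and the per-feature contribution reported to the
user is ``c_i = beta_i x_i / sum_j beta_j x_j`` (signed variant; the
``positive_only`` variant keeps the terms with ``beta_i x_i > 0`` and
renormalizes, so contributions are nonnegative and sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateFitError, UndefinedMetricError
from .features import DEFAULT_MODEL_FEATURES, FEATURE_NAMES, FeatureVector
from .types import FittedModel

DEFAULT_PH_THRESHOLD = 7.05
DEFAULT_L2_C = 1e4  # weak regularization; guards against perfect separation


@dataclass
class LabeledDataset:
    """Feature vectors with binary acidosis outcomes and center tags."""

    case_ids: list[str]
    features: list[FeatureVector]
    outcomes: np.ndarray  # boolean, True = pathological (pH < threshold)
    centers: list[str] = field(default_factory=list)
    outcome_threshold: float = DEFAULT_PH_THRESHOLD

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=bool)
        if not self.centers:
            self.centers = ["default"] * len(self.case_ids)
        if not (len(self.case_ids) == len(self.features) == self.outcomes.size == len(self.centers)):
            raise ValueError("dataset columns must align")

    def __len__(self) -> int:
        return len(self.case_ids)

    def matrix(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        return np.vstack([fv.as_array(names) for fv in self.features])

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            case_ids=[self.case_ids[i] for i in idx],
            features=[self.features[i] for i in idx],
            outcomes=self.outcomes[idx],
            centers=[self.centers[i] for i in idx],
            outcome_threshold=self.outcome_threshold,
        )


@dataclass(frozen=True)
class Prediction:
    risk: float
    contributions: dict[str, float]
    variant: str  # "signed" | "positive_only"


def balanced_weights(outcomes: np.ndarray) -> np.ndarray:
    """Per-case weights ``N / (2 * N_class)``: each class sums to N/2."""
    y = np.asarray(outcomes, dtype=bool)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateFitError("both outcome classes are required")
    w = np.where(y, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


def fit(
    dataset: LabeledDataset,
    feature_subset: tuple[str, ...] = DEFAULT_MODEL_FEATURES,
    C: float = DEFAULT_L2_C,
    sample_weight: np.ndarray | None = None,
) -> FittedModel:
    """Fit the class-balanced logistic model on a feature subset.

    ``sample_weight`` overrides the default balanced weights (used e.g. to
    verify weighting equivalences); weights are always multiplied in via
    scikit-learn's ``sample_weight``.
    """
    unknown = [f for f in feature_subset if f not in FEATURE_NAMES]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    X = dataset.matrix(tuple(feature_subset))
    y = dataset.outcomes.astype(int)
    w = balanced_weights(dataset.outcomes) if sample_weight is None else np.asarray(sample_weight, float)
    center = np.average(X, axis=0, weights=None)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    # tight tolerance so algebraically equivalent reweightings of the data
    # reproduce the same coefficients to ~1e-7
    clf = LogisticRegression(C=C, max_iter=5000, tol=1e-8)
    clf.fit(Z, y, sample_weight=w)
    return FittedModel(
        feature_names=tuple(feature_subset),
        beta0=float(clf.intercept_[0]),
        beta=clf.coef_.ravel().copy(),
        center=center,
        scale=scale,
        outcome_threshold=dataset.outcome_threshold,
    )


def decision_terms(model: FittedModel, x: FeatureVector | dict[str, float]) -> np.ndarray:
    """The per-feature terms ``beta_i * x_i`` on the standardized scale."""
    if isinstance(x, FeatureVector):
        x = x.as_dict()
    try:
        raw = np.array([x[name] for name in model.feature_names], dtype=float)
    except KeyError as exc:
        raise KeyError(f"feature {exc} missing from input") from exc
    z = (raw - model.center) / model.scale
    return model.beta * z


def predict(
    model: FittedModel,
    x: FeatureVector | dict[str, float],
    variant: str = "positive_only",
) -> Prediction:
    """Risk of acidosis plus per-feature contributions.

    Signed contributions ``c_i = beta_i x_i / sum_j beta_j x_j`` sum to 1
    whenever the denominator is nonzero; the positive_only variant is
    restricted to positive terms and renormalized (all zero when no term
    is positive).
    """
    if variant not in ("signed", "positive_only"):
        raise ValueError("variant must be 'signed' or 'positive_only'")
    terms = decision_terms(model, x)
    eta = model.beta0 + terms.sum()
    risk = float(1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))))
    total = terms.sum()
    if variant == "signed":
        contrib = terms / total if total != 0 else np.zeros_like(terms)
        if total != 0:
            assert abs(contrib.sum() - 1.0) < 1e-9
    else:
        pos = np.clip(terms, 0.0, None)
        pos_total = pos.sum()
        contrib = pos / pos_total if pos_total > 0 else np.zeros_like(terms)
    return Prediction(
        risk=risk,
        contributions=dict(zip(model.feature_names, contrib.tolist())),
        variant=variant,
    )


def predict_scores(model: FittedModel, dataset: LabeledDataset) -> np.ndarray:
    """Vectorized risk scores for a whole dataset."""
    X = dataset.matrix(model.feature_names)
    Z = (X - model.center) / model.scale
    eta = model.beta0 + Z @ model.beta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney): P(score+ > score-) with ties at 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: one class absent")
    # midranks handle ties exactly
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(y.size)
    sorted_s = s[order]
    i = 0
    k = 0
    while i < y.size:
        j = i
        while j < y.size and sorted_s[j] == sorted_s[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
        k += 1
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def weighted_auc(scores: np.ndarray, pos_weight: np.ndarray, neg_weight: np.ndarray) -> float:
    """AUC where each case i carries weight ``pos_weight[i]`` as a positive
    and ``neg_weight[i]`` as a negative (soft labels); ties count 1/2.

    With ``pos_weight = p_i`` (the true outcome probability) this is the
    Bayes-optimal AUC of a score against fresh label draws.
    """
    s = np.asarray(scores, float)
    wp = np.asarray(pos_weight, float)
    wn = np.asarray(neg_weight, float)
    order = np.argsort(s, kind="mergesort")
    s, wp, wn = s[order], wp[order], wn[order]
    # group ties
    boundaries = np.flatnonzero(np.diff(s)) + 1
    wp_g = np.add.reduceat(wp, np.concatenate(([0], boundaries)))
    wn_g = np.add.reduceat(wn, np.concatenate(([0], boundaries)))
    cum_neg = np.concatenate(([0.0], np.cumsum(wn_g)))[:-1]  # neg weight strictly below
    num = np.sum(wp_g * (cum_neg + 0.5 * wn_g))
    den = wp_g.sum() * wn_g.sum()
    if den == 0:
        raise UndefinedMetricError("AUC undefined: zero total weight in a class")
    return float(num / den)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per case; both classes spread round-robin after a shuffle."""
    y = np.asarray(y, dtype=bool)
    folds = np.empty(y.size, dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise DegenerateFitError(
                f"class with {idx.size} cases cannot be split into {k} folds"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def kfold_eval(
    dataset: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    feature_subset: tuple[str, ...] = DEFAULT_MODEL_FEATURES,
    C: float = DEFAULT_L2_C,
) -> dict:
    """Stratified k-fold cross-validation.

    Returns per-fold AUCs, the AUC of the pooled out-of-fold scores, the
    training AUC averaged across folds, and the fold assignment.
    """
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(dataset.outcomes, k, rng)
    oof = np.empty(len(dataset))
    fold_aucs, train_aucs = [], []
    for f in range(k):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        m = fit(dataset.subset(tr), feature_subset, C=C)
        oof[te] = predict_scores(m, dataset.subset(te))
        fold_aucs.append(auc(oof[te], dataset.outcomes[te]))
        train_aucs.append(auc(predict_scores(m, dataset.subset(tr)), dataset.outcomes[tr]))
    return {
        "fold_aucs": fold_aucs,
        "pooled_auc": auc(oof, dataset.outcomes),
        "train_auc_mean": float(np.mean(train_aucs)),
        "folds": folds,
        "oof_scores": oof,
    }


def cross_center_eval(
    dataset: LabeledDataset,
    feature_subset: tuple[str, ...] = DEFAULT_MODEL_FEATURES,
    C: float = DEFAULT_L2_C,
    skip_undefined: bool = False,
) -> dict[str, float]:
    """Leave-one-center-out evaluation: for each center, train on all other
    centers and report the held-out AUC.  A held-out center with a single
    outcome class raises (or reports NaN when ``skip_undefined``)."""
    centers = np.asarray(dataset.centers)
    uniq = sorted(set(dataset.centers))
    if len(uniq) < 2:
        raise DegenerateFitError("need at least 2 centers")
    out: dict[str, float] = {}
    for c in uniq:
        te = np.flatnonzero(centers == c)
        tr = np.flatnonzero(centers != c)
        assert not set(np.array(dataset.case_ids)[te]) & set(np.array(dataset.case_ids)[tr])
        m = fit(dataset.subset(tr), feature_subset, C=C)
        y_te = dataset.outcomes[te]
        try:
            out[c] = auc(predict_scores(m, dataset.subset(te)), y_te)
        except UndefinedMetricError:
            if not skip_undefined:
                raise
            out[c] = float("nan")
    return out
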