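"""Training and evaluation machinery: min-max scaling, recursive feature
elimination, classifier backends, stratified five-fold cross-validation, and
the threshold-dependent / threshold-independent performance measures.

The data-dependent chain (PSTNP table, scaler, feature selection, classifier)
is always fitted on training data only; :func:`cross_validate` refits the
entire chain inside every fold so no information leaks from held-out
sequences into the encoders or the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encoders import EncoderConfig, FeatureMatrix, PSTNPTable, encode_all, pstnp_fit
from .seqio import NucleotideSequence

CLASSIFIER_KINDS = ("DT", "RF", "KNN", "XGB", "GNB", "SVM")

MODEL_FORMAT_VERSION = "promoter70-model-1"


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalerParams:
    """Per-feature min/max observed on the training matrix."""

    feature_names: list[str]
    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.max_ < self.min_):
            raise ValueError("max < min in scaler parameters")


def minmax_fit(train: FeatureMatrix) -> ScalerParams:
    sc = MinMaxScaler().fit(train.values)
    return ScalerParams(list(train.feature_names), sc.data_min_, sc.data_max_)


def minmax_apply(m: FeatureMatrix, p: ScalerParams) -> FeatureMatrix:
    """Apply ``x' = (x - min) / (max - min)``.

    A feature that was constant in training maps everything to 0; held-out
    values may fall outside [0, 1] and are not clipped.
    """
    if list(m.feature_names) != list(p.feature_names):
        missing = set(p.feature_names) - set(m.feature_names)
        extra = set(m.feature_names) - set(p.feature_names)
        raise ValueError(
            f"feature name mismatch (missing: {sorted(missing)[:5]}, "
            f"extra: {sorted(extra)[:5]})"
        )
    rng = p.max_ - p.min_
    rng = np.where(rng == 0, 1.0, rng)
    return FeatureMatrix(
        list(m.feature_names), (m.values - p.min_) / rng, list(m.sequence_ids)
    )


# ---------------------------------------------------------------------------
# feature selection


@dataclass
class SelectionResult:
    """Outcome of recursive feature elimination.

    ``ranking`` maps every feature name to its elimination rank (1 = retained
    to the end); ``selected`` lists the surviving feature names in matrix
    column order; ``estimator_summary`` holds the coefficients of the final
    estimator fit on the survivors.
    """

    ranking: dict[str, int]
    selected: list[str]
    estimator_summary: np.ndarray


def _rfe_estimator(seed: int) -> LogisticRegression:
    # L2-penalized logistic regression with a deterministic solver; ranking
    # by (squared == absolute) coefficient magnitude.
    return LogisticRegression(C=1.0, max_iter=2000, solver="lbfgs", random_state=seed)


def rfe_select(
    X: FeatureMatrix,
    y: np.ndarray,
    n_target: int = 200,
    step: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination down to ``n_target`` features.

    Each round fits a logistic-regression estimator on the surviving
    features, ranks them by absolute coefficient, and drops the
    ``min(step, surviving - n_target)`` weakest, until exactly ``n_target``
    survive.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if n_target >= len(X.feature_names):
        raise ValueError("n_target must be smaller than the number of features")
    rfe = RFE(_rfe_estimator(seed), n_features_to_select=n_target, step=step)
    rfe.fit(X.values, y)
    ranking = dict(zip(X.feature_names, (int(r) for r in rfe.ranking_)))
    selected = [n for n, keep in zip(X.feature_names, rfe.support_) if keep]
    return SelectionResult(ranking, selected, rfe.estimator_.coef_.ravel().copy())


def rank_importance_rf(
    X: FeatureMatrix, y: np.ndarray, top_k: int = 20, seed: int = 0
):
    """Random-forest impurity importances, descending; ties broken by
    feature-name order. Returns a list of (name, importance)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf.fit(X.values, y)
    pairs = sorted(
        zip(X.feature_names, rf.feature_importances_), key=lambda p: (-p[1], p[0])
    )
    return pairs[:top_k]


# ---------------------------------------------------------------------------
# classifiers


class Scorer:
    """Fitted classifier exposing promoter-propensity scores in [0, 1]."""

    def __init__(self, kind: str, clf, hyperparameters: dict):
        self.kind = kind
        self.clf = clf
        self.hyperparameters = hyperparameters

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return np.clip(proba, 0.0, 1.0)


def _calibrated_svc(C, gamma, seed: int):
    # Platt-calibrated RBF SVC so the reported score is a probability in [0, 1]
    from sklearn.calibration import CalibratedClassifierCV

    return CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed),
        method="sigmoid",
        ensemble=False,
    )


def _svm_grid_search(X, y, seed: int):
    """Small inner grid over (C, gamma) selected by 5-fold accuracy; the
    winner is refit with Platt probability estimates so scores lie in [0, 1]."""
    grid = [
        (C, gamma)
        for C in (1.0, 10.0, 100.0)
        for gamma in ("scale", 0.01, 0.001)
    ]
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    best, best_acc = grid[0], -1.0
    for C, gamma in grid:
        accs = []
        for tr, te in inner.split(X, y):
            clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best, best_acc = (C, gamma), acc
    C, gamma = best
    final = _calibrated_svc(C, gamma, seed)
    final.fit(X, y)
    return final, {"kernel": "rbf", "C": C, "gamma": gamma, "inner_cv_accuracy": best_acc}


def train_classifier(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    kind: str = "SVM",
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> Scorer:
    """Fit one of the supported classifier backends and wrap it as a scorer.

    Supported kinds: DT, RF, KNN, XGB, GNB, SVM (default). The SVM backend
    runs a small inner grid search unless explicit hyperparameters are given.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; valid: {CLASSIFIER_KINDS}")
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    hp = dict(hyperparameters or {})
    if kind == "DT":
        clf = DecisionTreeClassifier(random_state=seed, **hp)
    elif kind == "RF":
        clf = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 200),
                                     random_state=seed, **hp)
    elif kind == "KNN":
        clf = KNeighborsClassifier(**(hp or {"n_neighbors": 5}))
    elif kind == "GNB":
        clf = GaussianNB(**hp)
    elif kind == "XGB":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=hp.pop("n_estimators", 200),
            random_state=seed,
            eval_metric="logloss",
            **hp,
        )
    elif kind == "SVM":
        if hp:
            clf = _calibrated_svc(hp.get("C", 1.0), hp.get("gamma", "scale"), seed)
        else:
            clf, hp = _svm_grid_search(Xv, y, seed)
    if kind != "SVM" or hyperparameters:
        clf.fit(Xv, y)
    return Scorer(kind, clf, hp)


# ---------------------------------------------------------------------------
# performance measures


@dataclass
class ConfusionCounts:
    """True/false positive and negative tallies feeding the closed-form
    performance measures."""

    P_T: int
    P_F: int
    N_T: int
    N_F: int

    @property
    def total(self) -> int:
        return self.P_T + self.P_F + self.N_T + self.N_F


@dataclass
class MetricSet:
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    mcc: float
    auroc: float | None = None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "mcc": self.mcc,
        }


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, t: float
) -> ConfusionCounts:
    """Tally a confusion matrix calling score >= t positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= t
    return ConfusionCounts(
        P_T=int(np.sum(pred & (labels == 1))),
        P_F=int(np.sum(pred & (labels == 0))),
        N_T=int(np.sum(~pred & (labels == 0))),
        N_F=int(np.sum(~pred & (labels == 1))),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Closed-form sensitivity/specificity/accuracy (percent) and Matthews
    correlation coefficient from confusion counts.

    sensitivity = 100 * P_T / (P_T + N_F)
    specificity = 100 * N_T / (N_T + P_F)
    accuracy    = 100 * (P_T + N_T) / total
    MCC = (P_T*N_T - P_F*N_F) / sqrt((P_T+P_F)(P_T+N_F)(N_T+P_F)(N_T+N_F))

    Zero denominators follow the usual conventions: an empty class leaves its
    rate at 0, and a zero factor in the MCC denominator gives MCC = 0.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    sens = 100.0 * c.P_T / (c.P_T + c.N_F) if c.P_T + c.N_F else 0.0
    spec = 100.0 * c.N_T / (c.N_T + c.P_F) if c.N_T + c.P_F else 0.0
    acc = 100.0 * (c.P_T + c.N_T) / c.total
    denom = (
        (c.P_T + c.P_F) * (c.P_T + c.N_F) * (c.N_T + c.P_F) * (c.N_T + c.N_F)
    )
    mcc = (c.P_T * c.N_T - c.P_F * c.N_F) / math.sqrt(denom) if denom else 0.0
    return MetricSet(sens, spec, acc, mcc)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; equals the Mann-Whitney statistic
    Pr(score+ > score-) + 0.5 * Pr(tie)."""
    return float(roc_auc_score(np.asarray(labels).astype(int), np.asarray(scores)))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricSet:
    m = metrics_from_counts(confusion_at_threshold(scores, labels, threshold))
    m.auroc = auroc(scores, labels)
    return m


def mean_metrics(sets: list[MetricSet]) -> MetricSet:
    return MetricSet(
        sensitivity=float(np.mean([m.sensitivity for m in sets])),
        specificity=float(np.mean([m.specificity for m in sets])),
        accuracy=float(np.mean([m.accuracy for m in sets])),
        mcc=float(np.mean([m.mcc for m in sets])),
        auroc=float(np.mean([m.auroc for m in sets])),
    )


# ---------------------------------------------------------------------------
# full training chain and cross-validation


@dataclass
class TrainedModel:
    """Self-contained bundle needed to score new sequences."""

    classifier_kind: str
    hyperparameters: dict
    encoder_cfg: EncoderConfig
    pstnp: PSTNPTable
    scaler: ScalerParams
    selection: SelectionResult
    scorer: Scorer
    default_threshold: float = 0.5
    training_metadata: dict = field(default_factory=dict)

    def score_matrix(self, m: FeatureMatrix) -> np.ndarray:
        scaled = minmax_apply(m, self.scaler)
        return self.scorer.score_samples(scaled.subset(self.selection.selected).values)

    def score_sequences(self, seqs: list[NucleotideSequence]) -> np.ndarray:
        return self.score_matrix(encode_all(seqs, self.encoder_cfg, self.pstnp))


def fit_chain(
    pos: list[NucleotideSequence],
    neg: list[NucleotideSequence],
    cfg: EncoderConfig,
    kind: str = "SVM",
    n_features: int = 200,
    step: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    hyperparameters: dict | None = None,
) -> TrainedModel:
    """Fit the full chain (PSTNP -> encode -> scale -> RFE -> classifier) on
    a labeled training set."""
    table = pstnp_fit(pos, neg)
    X = encode_all(list(pos) + list(neg), cfg, table)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    scaler = minmax_fit(X)
    Xs = minmax_apply(X, scaler)
    selection = rfe_select(Xs, y, n_target=n_features, step=step, seed=seed)
    scorer = train_classifier(
        Xs.subset(selection.selected).values, y, kind, hyperparameters, seed
    )
    return TrainedModel(
        classifier_kind=kind,
        hyperparameters=scorer.hyperparameters,
        encoder_cfg=cfg,
        pstnp=table,
        scaler=scaler,
        selection=selection,
        scorer=scorer,
        default_threshold=threshold,
        training_metadata={
            "seed": seed,
            "n_pos": len(pos),
            "n_neg": len(neg),
            "n_features_selected": n_features,
            "rfe_step": step,
        },
    )


@dataclass
class FoldResult:
    """Held-out evaluation of one cross-validation fold, including the
    fold-fitted artifacts (for leakage auditing)."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    pstnp: PSTNPTable
    scaler: ScalerParams
    selection: SelectionResult
    scores: np.ndarray
    labels: np.ndarray
    metrics: MetricSet


def cross_validate(
    pos: list[NucleotideSequence],
    neg: list[NucleotideSequence],
    cfg: EncoderConfig,
    kind: str = "SVM",
    k: int = 5,
    seed: int = 0,
    n_features: int = 200,
    step: int = 10,
    threshold: float = 0.5,
    hyperparameters: dict | None = None,
) -> tuple[list[FoldResult], MetricSet]:
    """Stratified k-fold cross-validation of the entire chain.

    The PSTNP table, scaler, feature selection and classifier are refitted on
    the k-1 training folds of every split and applied to the held-out fold
    only; the returned per-fold artifacts are exactly what that refit
    produced.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pos) < k or len(neg) < k:
        raise ValueError(f"each class needs at least k={k} members")
    seqs = list(pos) + list(neg)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(seqs)), y), start=1):
        tr_pos = [seqs[i] for i in tr if y[i] == 1]
        tr_neg = [seqs[i] for i in tr if y[i] == 0]
        table = pstnp_fit(tr_pos, tr_neg)
        X_tr = encode_all([seqs[i] for i in tr], cfg, table)
        X_te = encode_all([seqs[i] for i in te], cfg, table)
        scaler = minmax_fit(X_tr)
        Xs_tr = minmax_apply(X_tr, scaler)
        Xs_te = minmax_apply(X_te, scaler)
        selection = rfe_select(Xs_tr, y[tr], n_target=n_features, step=step, seed=seed)
        scorer = train_classifier(
            Xs_tr.subset(selection.selected).values, y[tr], kind, hyperparameters, seed
        )
        scores = scorer.score_samples(Xs_te.subset(selection.selected).values)
        folds.append(
            FoldResult(
                fold=fold,
                train_idx=tr,
                test_idx=te,
                pstnp=table,
                scaler=scaler,
                selection=selection,
                scores=scores,
                labels=y[te],
                metrics=evaluate_scores(scores, y[te], threshold),
            )
        )
    return folds, mean_metrics([f.metrics for f in folds])


# ---------------------------------------------------------------------------
# persistence


def save_model(m: TrainedModel, path) -> None:
    """Persist a trained model as a single self-describing archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classifier_kind": m.classifier_kind,
        "hyperparameters": m.hyperparameters,
        "encoder_cfg": m.encoder_cfg,
        "pstnp_z": m.pstnp.z,
        "scaler": m.scaler,
        "selection": m.selection,
        "scorer": m.scorer,
        "default_threshold": m.default_threshold,
        "training_metadata": m.training_metadata,
        "selected_feature_names": list(m.selection.selected),
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / truncated archive
        raise ValueError(f"cannot load model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive format: {payload.get('format_version', '?') if isinstance(payload, dict) else type(payload)}"
        )
    return TrainedModel(
        classifier_kind=payload["classifier_kind"],
        hyperparameters=payload["hyperparameters"],
        encoder_cfg=payload["encoder_cfg"],
        pstnp=PSTNPTable(payload["pstnp_z"]),
        scaler=payload["scaler"],
        selection=payload["selection"],
        scorer=payload["scorer"],
        default_threshold=payload["default_threshold"],
        training_metadata=payload["training_metadata"],
    )
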