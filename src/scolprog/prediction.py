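"""Two-phase classification experiment for progression prediction.

Phase 1 (*pre-selection*): six binary classifiers — support vector machine
(SVM), predictive discriminant analysis (PDA), naive Bayes (BAY), decision
tree (DET), k-nearest neighbours (KNN) and a bagged-tree ensemble (ENS) —
are screened by 10 repetitions of stratified 4-fold cross-validation,
giving 40 accuracy values per classifier.  All classifiers see identical
folds.

Phase 2 (*comparison*): the selected classifiers are evaluated on 100
stratified 80/20 train/test splits, for both predictor sets (the 12
anthropometric + geometrical predictors, and the 23-predictor set adding
the 11 biomechanical ones); sensitivity is the correctly-identified
progressive rate and specificity the correctly-identified stable rate.
Splits are shared across classifiers and predictor sets so the reduced/full
contrast is paired.

Predictors are used in their original scale (no standardization); sex and
Lenke type are dummy-encoded against a reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .calibration import BIOMECH_COLUMNS, FEATURE_COLUMNS

__all__ = [
    "REDUCED_COLUMNS", "FULL_COLUMNS", "ALGORITHMS", "PredictorSet",
    "HarnessResult", "KernelNaiveBayes", "ShrinkageDiscriminant",
    "make_classifier", "assemble_predictors", "preselect", "compare_models",
    "det_importance", "cv_folds", "holdout_splits",
]

REDUCED_COLUMNS = [c for c in FEATURE_COLUMNS if c not in BIOMECH_COLUMNS]
FULL_COLUMNS = list(FEATURE_COLUMNS)

CATEGORICAL = {"sex": ["F", "M"], "lenke_type": [1, 2, 3, 4, 5, 6]}

POSITIVE_CLASS = "progressive"


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density likelihoods.

    Bandwidths use a Silverman rule on the pooled (all-class) feature
    spread, scaled by the class sample size.  Sharing the spread across
    classes keeps kernel heights comparable: a feature that is nearly
    constant within one class — a dummy level absent from one group —
    would otherwise produce a density spike that overwhelms every other
    feature.
    """

    def __init__(self, bandwidth_scale: float = 0.9):
        self.bandwidth_scale = bandwidth_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        sd = X.std(axis=0, ddof=1)
        iqr = np.subtract(*np.percentile(X, [75, 25], axis=0))
        spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
        spread = np.maximum(spread, 1e-9 * (1.0 + np.abs(X).max(axis=0)))
        self.train_ = {}
        self.bandwidth_ = {}
        self.log_prior_ = {}
        for c in self.classes_:
            Xc = X[y == c]
            n = len(Xc)
            self.train_[c] = Xc
            self.bandwidth_[c] = self.bandwidth_scale * spread * n ** (-0.2)
            self.log_prior_[c] = np.log(n / len(X))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            Xc, h = self.train_[c], self.bandwidth_[c]
            # (n_test, n_train, n_feat) kernel log-densities
            z = (X[:, None, :] - Xc[None, :, :]) / h
            logk = -0.5 * z ** 2 - np.log(h * np.sqrt(2 * np.pi))
            feat_ll = logsumexp(logk, axis=1) - np.log(len(Xc))
            out[:, j] = self.log_prior_[c] + feat_ll.sum(axis=1)
        return out

    def predict(self, X):
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))


class ShrinkageDiscriminant(BaseEstimator, ClassifierMixin):
    """Linear discriminant with regularization toward the diagonal of the
    pooled covariance: Sigma_gamma = (1 - gamma) Sigma + gamma diag(Sigma).

    Diagonal (rather than scaled-identity) shrinkage keeps the classifier
    scale-equivariant per feature, which matters because predictors are
    used unstandardized.
    """

    def __init__(self, gamma: float = 0.6):
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = X.shape
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        pooled = np.zeros((p, p))
        for c, mu in zip(self.classes_, self.means_):
            d = X[y == c] - mu
            pooled += d.T @ d
        pooled /= max(n - len(self.classes_), 1)
        cov = (1.0 - self.gamma) * pooled + self.gamma * np.diag(np.diag(pooled))
        cov += 1e-8 * np.trace(cov) / p * np.eye(p)   # guard exact singularity
        self.precision_ = np.linalg.pinv(cov)
        return self

    def decision_scores(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((len(X), len(self.classes_)))
        for j, (mu, pi) in enumerate(zip(self.means_, self.priors_)):
            w = self.precision_ @ mu
            scores[:, j] = X @ w - 0.5 * mu @ w + np.log(pi)
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


#: Tuned hyperparameters of the six screened classifiers.
ALGORITHMS = ("SVM", "PDA", "BAY", "DET", "KNN", "ENS")


def make_classifier(name: str, random_state: int = 0):
    """Fresh estimator with the tuned hyperparameters.

    SVM: linear kernel, box constraint 10.  PDA: linear discriminant with
    shrinkage 0.6 toward the scaled identity.  BAY: kernel-density naive
    Bayes.  DET: tree capped at 4 splits (5 leaves).  KNN: 7 neighbours.
    ENS: bagging of 30 trees.
    """
    if name == "SVM":
        return SVC(kernel="linear", C=10.0)
    if name == "PDA":
        return ShrinkageDiscriminant(gamma=0.6)
    if name == "BAY":
        return KernelNaiveBayes()
    if name == "DET":
        return DecisionTreeClassifier(max_leaf_nodes=5, random_state=random_state)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=7)
    if name == "ENS":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=random_state),
            n_estimators=30, random_state=random_state)
    raise KeyError(f"unknown algorithm {name!r}")


@dataclass
class PredictorSet:
    name: str                       # 'reduced' | 'full'
    columns: list                   # predictor names before encoding
    encoded_columns: list
    matrix: np.ndarray              # subjects x encoded columns
    labels: np.ndarray              # 'stable' | 'progressive'


@dataclass
class HarnessResult:
    accuracy: dict = field(default_factory=dict)        # alg -> (40,)
    sensitivity: dict = field(default_factory=dict)     # (alg, set) -> (n_iter,)
    specificity: dict = field(default_factory=dict)
    importance: dict = field(default_factory=dict)      # predictor -> score
    pvalues: dict = field(default_factory=dict)


def _dummy_encode(df: pd.DataFrame, columns) -> tuple:
    """Reference-level (k-1) dummy coding of the categorical predictors;
    levels absent from the data are dropped, so a single-level categorical
    contributes no columns."""
    enc_cols, mats = [], []
    for col in columns:
        if col in CATEGORICAL:
            present = [lvl for lvl in CATEGORICAL[col]
                       if (df[col] == lvl).any()]
            for lvl in present[1:]:             # first present level = reference
                enc_cols.append(f"{col}_{lvl}")
                mats.append((df[col] == lvl).to_numpy(float))
        else:
            enc_cols.append(col)
            mats.append(df[col].to_numpy(float))
    return enc_cols, np.column_stack(mats) if mats else np.empty((len(df), 0))


def assemble_predictors(features: pd.DataFrame, set_name: str) -> PredictorSet:
    """Build the reduced (12-predictor) or full (23-predictor) design.

    ``features`` must carry a ``group`` label column plus all predictor
    columns of the requested set.
    """
    columns = {"reduced": REDUCED_COLUMNS, "full": FULL_COLUMNS}[set_name]
    missing = [c for c in columns + ["group"] if c not in features.columns]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    enc_cols, X = _dummy_encode(features, columns)
    return PredictorSet(
        name=set_name, columns=list(columns), encoded_columns=enc_cols,
        matrix=X, labels=features["group"].to_numpy())


def _check_split(y, train_idx):
    if len(np.unique(y[train_idx])) < 2:
        raise RuntimeError("stratification bug: a class is absent from a "
                           "training split")


def cv_folds(y, n_rep: int = 10, k: int = 4, seed: int = 0):
    """Shared stratified folds for the pre-selection phase: ``n_rep``
    independent shuffles, each split into ``k`` class-stratified folds."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_rep):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            _check_split(y, train_idx)
            folds.append((rep_seed, train_idx, test_idx))
    return folds


def holdout_splits(y, n_iter: int = 100, train_frac: float = 0.8, seed: int = 0):
    """Shared stratified train/test splits for the comparison phase."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_iter):
        it_seed = int(rng.integers(0, 2 ** 31 - 1))
        sss = StratifiedShuffleSplit(n_splits=1, test_size=1.0 - train_frac,
                                     random_state=it_seed)
        train_idx, test_idx = next(sss.split(np.zeros(len(y)), y))
        _check_split(y, train_idx)
        splits.append((it_seed, train_idx, test_idx))
    return splits


def preselect(predictors: PredictorSet, algorithms=ALGORITHMS,
              n_rep: int = 10, k: int = 4, seed: int = 0) -> HarnessResult:
    """Pre-selection phase: repeated stratified k-fold accuracy screening.

    Every repetition reshuffles the cohort into ``k`` stratified folds
    (15 stable / 10 progressive per fold at the reference 60/40 size of
    n=100); the same folds are used for every algorithm.
    """
    X, y = predictors.matrix, predictors.labels
    result = HarnessResult()
    acc = {alg: [] for alg in algorithms}
    for rep_seed, train_idx, test_idx in cv_folds(y, n_rep, k, seed):
        for alg in algorithms:
            clf = make_classifier(alg, random_state=rep_seed)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            acc[alg].append(float(np.mean(pred == y[test_idx])))
    result.accuracy = {alg: np.asarray(v) for alg, v in acc.items()}
    return result


def compare_models(reduced: PredictorSet, full: PredictorSet,
                   algorithms=("PDA", "BAY", "ENS"), n_iter: int = 100,
                   train_frac: float = 0.8, seed: int = 0) -> HarnessResult:
    """Comparison phase: repeated stratified holdout evaluation of the
    reduced vs full predictor sets with the selected algorithms.

    Train/test indices are identical across algorithms and predictor sets
    within an iteration, so reduced/full performance is paired.
    """
    if not np.array_equal(reduced.labels, full.labels):
        raise ValueError("predictor sets must describe the same subjects")
    y = reduced.labels
    result = HarnessResult()
    sens = {(alg, s): [] for alg in algorithms for s in ("reduced", "full")}
    spec = {(alg, s): [] for alg in algorithms for s in ("reduced", "full")}
    for it_seed, train_idx, test_idx in holdout_splits(y, n_iter, train_frac, seed):
        for ps in (reduced, full):
            X = ps.matrix
            for alg in algorithms:
                clf = make_classifier(alg, random_state=it_seed)
                clf.fit(X[train_idx], y[train_idx])
                pred = clf.predict(X[test_idx])
                truth = y[test_idx]
                prog = truth == POSITIVE_CLASS
                sens[(alg, ps.name)].append(float(np.mean(pred[prog] == POSITIVE_CLASS)))
                spec[(alg, ps.name)].append(float(np.mean(pred[~prog] == "stable")))
    result.sensitivity = {k2: np.asarray(v) for k2, v in sens.items()}
    result.specificity = {k2: np.asarray(v) for k2, v in spec.items()}
    return result


def det_importance(tree: DecisionTreeClassifier, feature_names=None) -> dict:
    """Decision-tree predictor importance: for every predictor, the summed
    change in mean squared error due to splits on it, divided by the number
    of branch nodes.  Predictors never used in a split score zero; a stump
    with no branch node scores all-zero.

    Node MSE is the variance of the binary outcome within the node.
    """
    t = tree.tree_
    n_features = t.n_features
    names = list(feature_names) if feature_names is not None else list(range(n_features))
    scores = np.zeros(n_features)

    def node_mse(n):
        counts = t.value[n].ravel() * t.weighted_n_node_samples[n]
        total = counts.sum()
        p = counts[-1] / total if total > 0 else 0.0
        return p * (1.0 - p)

    n_branch = 0
    w_root = t.weighted_n_node_samples[0]
    for n in range(t.node_count):
        left, right = t.children_left[n], t.children_right[n]
        if left == -1:
            continue
        n_branch += 1
        w, wl, wr = (t.weighted_n_node_samples[n],
                     t.weighted_n_node_samples[left],
                     t.weighted_n_node_samples[right])
        delta = (w * node_mse(n) - wl * node_mse(left)
                 - wr * node_mse(right)) / w_root
        scores[t.feature[n]] += delta
    if n_branch > 0:
        scores /= n_branch
    return {names[i]: float(scores[i]) for i in range(n_features)}
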