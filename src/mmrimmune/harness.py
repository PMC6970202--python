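"""Balanced-subset predictive-modeling harness.

Reproduces the study's machine-learning procedure on any cohort: draw an
equal-class subset (75 observations for the three molecular classes at
sizes 25/33/35; 70 for the pooled two-class MMR-deficient vs proficient
design), split it into exactly stratified train/test partitions (50/20 for
two classes; 51/24 is the nearest exactly stratified analogue for three),
fit a model family with cross-validated hyperparameter selection on the
training subset only, and evaluate with confusion-matrix metrics, ROC
points, rank-statistic AUC and — for three classes — the Hand-Till
multiclass AUC M, the average of all pairwise one-vs-one rank AUCs.

Model families (scikit-learn under the hood): a single-hidden-layer
feed-forward neural network, a linear support vector machine, Fisher
(linear) discriminant analysis, and multinomial logistic regression.
Features are standardized (training-set statistics) for the NN and SVM,
raw for the discriminant and logit, unless overridden.

Tumors missing a feature (biopsies lack invasive-margin counts) are
dropped per feature set, with the exclusion count recorded on the result.
All randomness derives from one master seed via numpy SeedSequence
spawning, so every repeat is independently reproducible.
"""

from __future__ import annotations

import enum
import importlib.resources
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .records import Cohort, CohortLabel
from .scores import ScoreDefinition, population_sums, score_matrix

TWO_CLASS_LABELS = ("MMRD", "MMRP")


class ModelFamily(str, enum.Enum):
    FEEDFORWARD_NN = "FEEDFORWARD_NN"
    LINEAR_SVM = "LINEAR_SVM"
    FISHER_DISCRIMINANT = "FISHER_DISCRIMINANT"
    MULTINOMIAL_LOGIT = "MULTINOMIAL_LOGIT"


class Preprocessing(str, enum.Enum):
    NONE = "NONE"
    STANDARDIZE = "STANDARDIZE"


_DEFAULT_PREPROCESSING = {
    ModelFamily.FEEDFORWARD_NN: Preprocessing.STANDARDIZE,
    ModelFamily.LINEAR_SVM: Preprocessing.STANDARDIZE,
    ModelFamily.FISHER_DISCRIMINANT: Preprocessing.NONE,
    ModelFamily.MULTINOMIAL_LOGIT: Preprocessing.NONE,
}


@dataclass
class ModelSpec:
    family: ModelFamily
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0
    preprocessing: Optional[Preprocessing] = None

    def __post_init__(self) -> None:
        self.family = ModelFamily(self.family)
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.preprocessing is None:
            self.preprocessing = _DEFAULT_PREPROCESSING[self.family]
        else:
            self.preprocessing = Preprocessing(self.preprocessing)


@dataclass(frozen=True)
class FeatureSet:
    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError(f"feature set {self.name!r} is empty")


@dataclass
class EvalReport:
    classes: tuple
    confusion: np.ndarray            # rows = true class, cols = predicted
    accuracy: float
    auc: float
    multiclass: bool
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    roc_points: Optional[np.ndarray] = None  # (fpr, tpr) rows, binary only
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Subsetting and partitioning
# ---------------------------------------------------------------------------

def balanced_subset(
    labels: Sequence[object], classes: Optional[Sequence[object]] = None, seed: int = 0
) -> np.ndarray:
    """Equal-class index subset: m indices per class, m the minimum class
    size, sampled without replacement; deterministic per seed."""
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = sorted(set(labels.tolist()), key=str)
    rng = np.random.default_rng(seed)
    per_class_idx = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            raise ValueError(f"class {c!r} absent from labels")
        per_class_idx.append(idx)
    m = min(idx.size for idx in per_class_idx)
    chosen = [rng.choice(idx, size=m, replace=False) for idx in per_class_idx]
    return np.concatenate(chosen)


def partition(
    labels: Sequence[object], n_train: int, n_test: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exactly stratified, disjoint train/test split of all supplied indices.

    Each class contributes train and test quotas proportional to its size;
    sizes that do not stratify exactly raise with an explanation.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test = {n_train + n_test} != {n} observations")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == c)
        quota = n_train * idx.size / n
        if abs(quota - round(quota)) > 1e-9:
            raise ValueError(
                f"cannot stratify exactly: class {c!r} (size {idx.size}) would need "
                f"{quota:.2f} training observations; choose sizes divisible by the class ratio"
            )
        quota = int(round(quota))
        shuffled = rng.permutation(idx)
        train_parts.append(shuffled[:quota])
        test_parts.append(shuffled[quota:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

_DEFAULT_GRIDS = {
    ModelFamily.FEEDFORWARD_NN: {
        "model__hidden_layer_sizes": [(4,), (8,)],
        "model__alpha": [1e-4, 1e-1],
    },
    ModelFamily.LINEAR_SVM: {"model__C": [0.01, 0.1, 1.0, 10.0]},
    ModelFamily.FISHER_DISCRIMINANT: {},
    ModelFamily.MULTINOMIAL_LOGIT: {},
}


class FittedModel:
    """A fitted scorer: per-class continuous scores and argmax labels."""

    def __init__(self, estimator, classes: np.ndarray):
        self._estimator = estimator
        self.classes_ = classes

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        est = self._estimator
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(features))
        scores = np.asarray(est.decision_function(features))
        if scores.ndim == 1:  # binary margin -> two-column scores
            scores = np.column_stack([-scores, scores])
        return scores

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_scores(features), axis=1)]


def _build_estimator(spec: ModelSpec):
    seed = int(spec.seed) % (2**31)
    if spec.family is ModelFamily.FEEDFORWARD_NN:
        core = MLPClassifier(max_iter=3000, random_state=seed)
    elif spec.family is ModelFamily.LINEAR_SVM:
        core = SVC(kernel="linear", decision_function_shape="ovr", random_state=seed)
    elif spec.family is ModelFamily.FISHER_DISCRIMINANT:
        core = LinearDiscriminantAnalysis()
    else:
        core = LogisticRegression(max_iter=5000)
    steps = []
    if spec.preprocessing is Preprocessing.STANDARDIZE:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", core))
    return Pipeline(steps)


def train_model(features: np.ndarray, labels: Sequence[object], spec: ModelSpec) -> FittedModel:
    """Fit a model family; hyperparameters tuned by k-fold CV on the
    training data only. Deterministic per spec seed."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = np.array(sorted(set(labels.tolist()), key=str), dtype=object)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    pipeline = _build_estimator(spec)
    grid = dict(_DEFAULT_GRIDS[spec.family])
    grid.update(spec.hyperparameters)
    if grid:
        search = GridSearchCV(pipeline, grid, cv=spec.cv_folds, scoring="accuracy", n_jobs=1)
        search.fit(features, labels)
        estimator = search.best_estimator_
    else:
        estimator = pipeline.fit(features, labels)
    fitted_classes = estimator.named_steps["model"].classes_
    return FittedModel(estimator, np.asarray(fitted_classes, dtype=object))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def rank_auc(scores: Sequence[float], positive: Sequence[bool]) -> float:
    """Mann-Whitney rank AUC of a score for a binary outcome; tied scores
    contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def hand_till_auc(scores: np.ndarray, labels: Sequence[object],
                  classes: Optional[Sequence[object]] = None) -> float:
    """Hand-Till multiclass AUC M.

    M = 2/(c(c-1)) * sum over unordered class pairs {i,j} of
    A(i,j) = (A(i|j) + A(j|i)) / 2, where A(i|j) is the rank AUC of the
    class-i score separating class i from class j on observations of those
    two classes only. Reduces exactly to the binary rank AUC when c = 2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = sorted(set(labels.tolist()), key=str)
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if not np.any(labels == c):
            raise ValueError(f"class {c!r} absent from labels")
    total = 0.0
    for i, j in itertools.combinations(range(len(classes)), 2):
        mask = (labels == classes[i]) | (labels == classes[j])
        is_i = labels[mask] == classes[i]
        a_ij = rank_auc(scores[mask, i], is_i)
        a_ji = rank_auc(scores[mask, j], ~is_i)
        total += (a_ij + a_ji) / 2.0
    c = len(classes)
    return 2.0 * total / (c * (c - 1))


def _safe_ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def evaluate(
    model: FittedModel,
    features: np.ndarray,
    labels: Sequence[object],
    positive_class: Optional[object] = None,
) -> EvalReport:
    """Confusion matrix, derived metrics, ROC and AUC on a labeled test set.

    Binary AUC is the rank statistic over the positive-class score;
    three-or-more classes use the Hand-Till M. Metrics with a zero
    denominator are reported as None (undefined), never as 0.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = model.classes_
    scores = model.predict_scores(features)
    predicted = classes[np.argmax(scores, axis=1)]
    confusion = _sk_confusion(labels, predicted, labels=list(classes))
    accuracy = float(np.trace(confusion) / confusion.sum())
    multiclass = classes.size > 2
    if multiclass:
        auc = hand_till_auc(scores, labels, classes=list(classes))
        return EvalReport(tuple(classes), confusion, accuracy, auc, True)
    if positive_class is None:
        positive_class = classes[-1]
    pos_idx = int(np.flatnonzero(classes == positive_class)[0])
    neg_idx = 1 - pos_idx
    is_pos = labels == positive_class
    auc = rank_auc(scores[:, pos_idx], is_pos)
    tp = int(confusion[pos_idx, pos_idx])
    fn = int(confusion[pos_idx, neg_idx])
    tn = int(confusion[neg_idx, neg_idx])
    fp = int(confusion[neg_idx, pos_idx])
    fpr, tpr, _ = roc_curve(is_pos.astype(int), scores[:, pos_idx])
    return EvalReport(
        tuple(classes),
        confusion,
        accuracy,
        auc,
        False,
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, tn + fn),
        roc_points=np.column_stack([fpr, tpr]),
    )


def binary_metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity/PPV/NPV from raw confusion counts."""
    return {
        "sensitivity": _safe_ratio(tp, tp + fn),
        "specificity": _safe_ratio(tn, tn + fp),
        "ppv": _safe_ratio(tp, tp + fp),
        "npv": _safe_ratio(tn, tn + fn),
    }


# ---------------------------------------------------------------------------
# Feature sets and experiments
# ---------------------------------------------------------------------------

class FeatureMode(str, enum.Enum):
    TWO_CLASS = "TWO_CLASS"
    THREE_CLASS = "THREE_CLASS"


def enumerate_feature_sets(mode: FeatureMode, path=None) -> list[FeatureSet]:
    """The registry of raw-count feature sets.

    TWO_CLASS: the packaged 8 subsets of {CD3_CT, CD3_IM, CD8_CT, CD8_IM}
    (editable CSV). THREE_CLASS: a generated family of 32 subsets of the 10
    populations — every multi-marker subset with both compartments plus the
    tumor-center-only sets of >= 4 markers — sizes 4 to 10.
    """
    mode = FeatureMode(mode)
    if path is not None:
        frame = pd.read_csv(path)
        sets = [FeatureSet(r.name, tuple(r.columns.split(";"))) for r in frame.itertuples()]
    elif mode is FeatureMode.TWO_CLASS:
        with importlib.resources.files("mmrimmune.data").joinpath(
            "feature_sets_two_class.csv"
        ).open() as fh:
            frame = pd.read_csv(fh)
        sets = [FeatureSet(r.name, tuple(r.columns.split(";"))) for r in frame.itertuples()]
    else:
        markers = ["CD3", "CD8", "CD45RO", "FOXP3", "PD1"]
        sets = []
        for size in range(2, 6):
            for combo in itertools.combinations(markers, size):
                cols = tuple(f"{m}_{c}" for m in combo for c in ("CT", "IM"))
                sets.append(FeatureSet("+".join(combo) + ":CT+IM", cols))
        for size in (4, 5):
            for combo in itertools.combinations(markers, size):
                cols = tuple(f"{m}_CT" for m in combo)
                sets.append(FeatureSet("+".join(combo) + ":CT", cols))
    if not sets:
        raise ValueError("empty feature-set enumeration")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature-set names")
    return sets


def assemble_design(cohort: Cohort, registry: Optional[Sequence[ScoreDefinition]] = None) -> pd.DataFrame:
    """Design table: per tumor, cohort label + 10 raw population sums + the
    registry's immune scores (NaN where a compartment is missing)."""
    sums = population_sums(cohort)
    scores = score_matrix(cohort, registry)
    design = pd.concat([sums, scores], axis=1)
    design.insert(0, "cohort", [r.cohort.value for r in cohort])
    return design


@dataclass
class ExperimentResult:
    reports: list[EvalReport]
    feature_set: FeatureSet
    mode: FeatureMode
    seed: int
    n_excluded: int

    def summary(self) -> dict:
        aucs = np.array([r.auc for r in self.reports])
        accs = np.array([r.accuracy for r in self.reports])
        return {
            "n_repeats": len(self.reports),
            "mean_auc": float(aucs.mean()),
            "sd_auc": float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
            "mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
            "auc_q25": float(np.percentile(aucs, 25)),
            "auc_q75": float(np.percentile(aucs, 75)),
            "n_excluded": self.n_excluded,
        }


def _mode_labels(design: pd.DataFrame, mode: FeatureMode) -> np.ndarray:
    if mode is FeatureMode.THREE_CLASS:
        return design["cohort"].to_numpy(dtype=object)
    pooled = np.where(design["cohort"] == CohortLabel.MMRP.value, "MMRP", "MMRD")
    return pooled.astype(object)


def run_experiment(
    design: pd.DataFrame,
    feature_set: FeatureSet,
    spec: ModelSpec,
    mode: FeatureMode = FeatureMode.TWO_CLASS,
    n_repeats: int = 20,
    seed: int = 0,
    n_train: Optional[int] = None,
    n_test: Optional[int] = None,
) -> ExperimentResult:
    """Repeat balanced-subset -> stratified split -> train -> evaluate.

    Split sizes default to 50/20 (two-class) and 51/24 (three-class). Rows
    with a missing feature are dropped before subsetting and counted on the
    result. Train and test indices are asserted disjoint on every repeat.
    """
    mode = FeatureMode(mode)
    missing = [c for c in feature_set.columns if c not in design.columns]
    if missing:
        raise ValueError(f"feature set {feature_set.name!r}: unknown column(s) {missing}")
    usable = design.dropna(subset=list(feature_set.columns))
    n_excluded = len(design) - len(usable)
    features_all = usable[list(feature_set.columns)].to_numpy(dtype=float)
    labels_all = _mode_labels(usable, mode)
    if n_train is None or n_test is None:
        n_train, n_test = (50, 20) if mode is FeatureMode.TWO_CLASS else (51, 24)
    master = np.random.SeedSequence(seed)
    reports = []
    for child in master.spawn(n_repeats):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        subset = balanced_subset(labels_all, seed=sub_seed)
        sub_labels = labels_all[subset]
        total = len(subset)
        k = len(set(sub_labels.tolist()))
        # nearest exactly stratified analogue of the requested split
        per_class_train = int(round(n_train * (total / (n_train + n_test)) / k))
        tr = per_class_train * k
        te = total - tr
        if te < k:
            raise ValueError("test partition would miss a class; reduce n_train")
        train_rel, test_rel = partition(sub_labels, tr, te, seed=sub_seed + 1)
        train_idx, test_idx = subset[train_rel], subset[test_rel]
        assert not set(train_idx) & set(test_idx), "train/test leak"
        model = train_model(
            features_all[train_idx],
            labels_all[train_idx],
            ModelSpec(
                spec.family,
                dict(spec.hyperparameters),
                spec.cv_folds,
                seed=sub_seed,
                preprocessing=spec.preprocessing,
            ),
        )
        positive = "MMRD" if mode is FeatureMode.TWO_CLASS else None
        report = evaluate(model, features_all[test_idx], labels_all[test_idx], positive_class=positive)
        report.n_excluded = n_excluded
        reports.append(report)
    return ExperimentResult(reports, feature_set, mode, seed, n_excluded)
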