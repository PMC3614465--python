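"""Discriminative classification of indel candidates.

A soft-margin linear C-SVM is trained on validated feature vectors —
in production, candidates labeled by capillary resequencing; here,
truth-labeled synthetic ones.  Features are min-max
normalised to [0, 1] with bounds learned on training data only.  Model
selection follows a nested cross-validation: an outer stratified
k-fold estimates performance while an inner k-fold on each outer
training set picks the penalty C (decade grid 1e-5 .. 1e5) that
maximises the specificity-sensitivity break-even point (Spec-Sens-BEP,
the threshold-sweep operating point where the true-positive rate
equals the true-negative rate).

The linear kernel keeps the model interpretable: the sign of each
learned weight says whether a feature argues for or against a
candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import LabeledFeatureVector

__all__ = [
    "TrainingSet",
    "NormalizationBounds",
    "LinearModel",
    "CVReport",
    "DEFAULT_C_GRID",
    "DEFAULT_C",
    "fit_normalization",
    "apply_normalization",
    "train_svm",
    "auc",
    "spec_sens_bep",
    "select_c",
    "nested_cv",
    "predict",
    "weight_report",
    "save_model",
    "load_model",
]

DEFAULT_C_GRID = tuple(10.0**k for k in range(-5, 6))
# cross-validated best C for the two candidate types
DEFAULT_C = {"deletion": 10.0, "insertion": 0.10, "f1": 1.0}
DEFAULT_KFOLD = {"deletion": 10, "insertion": 5, "f1": 10}

MODEL_FORMAT_TAG = "svindel-linear-model-v1"

# bound on libsvm solver iterations: at extreme C on label-noise data the
# solver creeps toward an interior optimum for minutes without changing
# the decision function materially; the cap keeps grid searches cheap
SVC_MAX_ITER = 10_000


@dataclass
class TrainingSet:
    X: np.ndarray  # (n, d) raw (un-normalised) feature values
    y: np.ndarray  # (n,) labels in {+1, -1}
    feature_names: list[str]
    kind: str = "deletion"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes disagree")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length != number of columns")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[LabeledFeatureVector], kind: Optional[str] = None
    ) -> "TrainingSet":
        labeled = [v for v in vectors if v.label in (1, -1)]
        if not labeled:
            raise ValueError("no labeled vectors")
        names = labeled[0].feature_names
        X = np.array([v.values for v in labeled], dtype=float)
        y = np.array([v.label for v in labeled], dtype=int)
        return cls(X=X, y=y, feature_names=list(names), kind=kind or labeled[0].kind)


@dataclass
class NormalizationBounds:
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.minimum > self.maximum):
            raise ValueError("per-feature minimum exceeds maximum")


@dataclass
class LinearModel:
    """w . x_normalised + b, with the normalisation bounds baked in."""

    weights: np.ndarray
    bias: float
    C: float
    bounds: NormalizationBounds
    feature_names: list[str]
    kind: str = "deletion"
    seed: Optional[int] = None


@dataclass
class CVReport:
    aucs: list[float]
    beps: list[float]
    chosen_c: list[list[float]]  # per repeat, per outer fold
    fold_bounds: list[list[NormalizationBounds]] = field(default_factory=list)
    k: int = 0
    repeats: int = 0
    seed: Optional[int] = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    @property
    def mean_bep(self) -> float:
        return float(np.mean(self.beps))

    @property
    def sd_bep(self) -> float:
        return float(np.std(self.beps, ddof=1)) if len(self.beps) > 1 else 0.0


def fit_normalization(X: np.ndarray) -> NormalizationBounds:
    X = np.asarray(X, dtype=float)
    return NormalizationBounds(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_normalization(X: np.ndarray, bounds: NormalizationBounds) -> np.ndarray:
    """Affine map of each column to [0, 1]; values outside the training
    range are clipped, constant training columns map to 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    span = bounds.maximum - bounds.minimum
    out = np.zeros_like(X)
    nonconst = span > 0
    out[:, nonconst] = (X[:, nonconst] - bounds.minimum[nonconst]) / span[nonconst]
    return np.clip(out, 0.0, 1.0)


def train_svm(train: TrainingSet, C: Optional[float] = None) -> LinearModel:
    """Fit a linear C-SVM on min-max-normalised features."""
    classes = set(np.unique(train.y))
    if classes != {-1, 1}:
        raise ValueError("training set must contain both classes")
    if C is None:
        C = DEFAULT_C.get(train.kind, 1.0)
    if C <= 0:
        raise ValueError("C must be positive")
    bounds = fit_normalization(train.X)
    Xn = apply_normalization(train.X, bounds)
    svc = SVC(kernel="linear", C=C, max_iter=SVC_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Xn, train.y)
    return LinearModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=float(C),
        bounds=bounds,
        feature_names=list(train.feature_names),
        kind=train.kind,
    )


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to compute a metric")
    return pos, neg


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank statistic, ties averaged."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(np.asarray(labels))
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def spec_sens_bep(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Specificity-sensitivity break-even point.

    Sweep the decision threshold over every score (predict positive at
    score >= t, plus the all-negative extreme); return the true-
    positive rate at the threshold minimising |TPR - TNR|, taking the
    lower threshold on ties.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = _check_two_classes(y)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    uniq = np.unique(scores)  # ascending
    thresholds = np.concatenate([uniq, [np.inf]])
    best_gap, best_tpr = None, 0.0
    for t in thresholds:
        pred_pos = scores >= t
        tpr = float((pred_pos & pos).sum()) / n_pos
        tnr = float((~pred_pos & neg).sum()) / n_neg
        gap = abs(tpr - tnr)
        if best_gap is None or gap < best_gap:
            best_gap, best_tpr = gap, tpr
    return best_tpr


def _decision_values(model: LinearModel, X: np.ndarray) -> np.ndarray:
    Xn = apply_normalization(X, model.bounds)
    return Xn @ model.weights + model.bias


def select_c(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    c_grid: Sequence[float],
    rng: np.random.Generator,
    kind: str = "deletion",
) -> float:
    """Inner cross-validated C choice: the grid value with the highest
    mean inner-fold Spec-Sens-BEP (largest C on ties)."""
    inner = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    splits = list(inner.split(X, y))
    best_c, best_bep = None, -1.0
    for C in c_grid:
        beps = []
        for tr, te in splits:
            sub = TrainingSet(X=X[tr], y=y[tr], feature_names=[""] * X.shape[1], kind=kind)
            try:
                model = train_svm(sub, C=C)
            except ValueError:
                continue
            values = _decision_values(model, X[te])
            try:
                beps.append(spec_sens_bep(values, y[te]))
            except ValueError:
                continue
        mean_bep = float(np.mean(beps)) if beps else -1.0
        if mean_bep >= best_bep:
            best_bep, best_c = mean_bep, C
    return float(best_c)


def nested_cv(
    train: TrainingSet,
    k: Optional[int] = None,
    repeats: int = 100,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
) -> CVReport:
    """Repeated nested stratified cross-validation.

    Per repeat: an outer k-fold split; per outer fold, ``select_c``
    runs an inner k-fold on the outer training set only, the model is
    refit on the outer training set with the chosen C (normalisation
    bounds likewise fit on the outer training set only), and the outer
    test set is scored.  The pooled scores of one repeat give one AUC
    and one Spec-Sens-BEP; the report carries mean and sd over repeats.
    """
    if k is None:
        k = DEFAULT_KFOLD.get(train.kind, 10)
    if k < 2:
        raise ValueError("k must be >= 2")
    class_sizes = [int((train.y == c).sum()) for c in (-1, 1)]
    if min(class_sizes) < k:
        raise ValueError(
            f"smallest class has {min(class_sizes)} examples, fewer than k={k} "
            "stratified folds; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    report = CVReport(aucs=[], beps=[], chosen_c=[], fold_bounds=[], k=k,
                      repeats=repeats, seed=seed)
    for _ in range(repeats):
        outer = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        pooled_scores: list[float] = []
        pooled_labels: list[int] = []
        cs: list[float] = []
        bset: list[NormalizationBounds] = []
        for tr, te in outer.split(train.X, train.y):
            C = select_c(train.X[tr], train.y[tr], k, c_grid, rng, train.kind)
            sub = TrainingSet(
                X=train.X[tr],
                y=train.y[tr],
                feature_names=train.feature_names,
                kind=train.kind,
            )
            model = train_svm(sub, C=C)
            pooled_scores.extend(_decision_values(model, train.X[te]))
            pooled_labels.extend(train.y[te])
            cs.append(C)
            bset.append(model.bounds)
        report.aucs.append(auc(pooled_scores, pooled_labels))
        report.beps.append(spec_sens_bep(pooled_scores, pooled_labels))
        report.chosen_c.append(cs)
        report.fold_bounds.append(bset)
    return report


def predict(
    model: LinearModel,
    vectors: Sequence[LabeledFeatureVector],
) -> list[tuple[float, int]]:
    """(decision value, class) per vector; value >= 0 is the positive
    class."""
    if not vectors:
        return []
    for v in vectors:
        if v.feature_names != model.feature_names:
            missing = set(model.feature_names) - set(v.feature_names)
            extra = set(v.feature_names) - set(model.feature_names)
            raise ValueError(
                f"{v.candidate_id}: feature mismatch with model "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
            )
    X = np.array([v.values for v in vectors], dtype=float)
    values = _decision_values(model, X)
    return [(float(val), 1 if val >= 0 else -1) for val in values]


def weight_report(model: LinearModel) -> list[tuple[str, float]]:
    """Feature weights sorted by signed value, descending.  A positive
    weight argues for a candidate, a negative one against it."""
    pairs = list(zip(model.feature_names, (float(w) for w in model.weights)))
    return sorted(pairs, key=lambda kv: -kv[1])


def save_model(model: LinearModel, path: str) -> None:
    def fmt(arr) -> str:
        return "\t".join(repr(float(x)) for x in arr)

    with open(path, "w") as fh:
        fh.write(f"format\t{MODEL_FORMAT_TAG}\n")
        fh.write(f"kind\t{model.kind}\n")
        fh.write(f"C\t{model.C!r}\n")
        fh.write(f"seed\t{'' if model.seed is None else model.seed}\n")
        fh.write("features\t" + "\t".join(model.feature_names) + "\n")
        fh.write("weights\t" + fmt(model.weights) + "\n")
        fh.write(f"bias\t{model.bias!r}\n")
        fh.write("min\t" + fmt(model.bounds.minimum) + "\n")
        fh.write("max\t" + fmt(model.bounds.maximum) + "\n")


def load_model(path: str) -> LinearModel:
    fields: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            fields[parts[0]] = parts[1:]
    if fields.get("format", [""])[0] != MODEL_FORMAT_TAG:
        raise ValueError(f"{path}: not a recognised model file")
    seed_field = fields.get("seed", [""])[0]
    return LinearModel(
        weights=np.array([float(x) for x in fields["weights"]]),
        bias=float(fields["bias"][0]),
        C=float(fields["C"][0]),
        bounds=NormalizationBounds(
            minimum=np.array([float(x) for x in fields["min"]]),
            maximum=np.array([float(x) for x in fields["max"]]),
        ),
        feature_names=fields["features"],
        kind=fields["kind"][0],
        seed=int(seed_field) if seed_field else None,
    )
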