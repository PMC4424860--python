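"""Boundary-constrained RBF-SVM two-class model for component classification.

The classifier separates resting-state functional networks (RFN, the
positive class, encoded 1) from artifact components (ART, encoded 0) in the
conditioned five-feature space.  The kernel is k(x, y) = exp(-sigma ||x - y||^2);
sigma defaults to a seeded draw between the 0.1 and 0.9 quantiles of the
inverse squared pairwise-distance statistic (the kernlab ``sigest``
heuristic), cost defaults to 100, and the error weight on the RFN class is
larger than on ART so that mistaking a true network for an artifact costs
more than the reverse.  Hyper-parameters can be confirmed by an exhaustive
grid search over C in [10, 1000] (step 10) and sigma in [0.1, 1.0]
(step 0.1), maximizing cross-validated accuracy subject to sensitivity 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .clusters import ThresholdSpec
from .data import ART, RFN, BinaryMask, ICASet, LabelTable
from .features import (
    DEFAULT_BAND,
    FEATURE_NAMES,
    ConditioningStats,
    extract_feature_table,
    fit_conditioning,
)

__all__ = [
    "ClassifierModel",
    "GridSearchSpec",
    "GridSearchResult",
    "ConfusionCounts",
    "ClassCounts",
    "ClassificationMetrics",
    "rbf_kernel",
    "kernel_matrix",
    "estimate_sigma",
    "train",
    "grid_search",
    "classify_set",
    "fit_conditioned",
    "metrics",
    "artifact_overlap_rate",
]

#: default per-class error weights (RFN, ART): errors on true RFNs cost more.
DEFAULT_CLASS_WEIGHTS = (10.0, 1.0)


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Radial basis kernel exp(-sigma ||x - y||^2), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(np.exp(-sigma * np.sum((x - y) ** 2)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise RBF kernel matrix between the rows of X and Y."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-sigma * d2)


def estimate_sigma(
    features: np.ndarray,
    quantile_lo: float = 0.1,
    quantile_hi: float = 0.9,
    seed: int | None = None,
    n_subsample: int = 100,
    midpoint: bool = False,
) -> float:
    """Sigma heuristic: quantiles of the inverse squared-distance statistic.

    Squared Euclidean distances between random pairs of a subsample are
    collected; good sigmas lie between the ``quantile_lo`` and
    ``quantile_hi`` quantiles of 1/d^2.  By default a seeded uniform draw
    within that bracket is returned; ``midpoint=True`` returns the bracket
    midpoint instead.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points to estimate sigma")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if n > n_subsample:
        X = X[rng.choice(n, size=n_subsample, replace=False)]
        n = n_subsample
    i = rng.integers(0, n, size=2 * n)
    j = rng.integers(0, n, size=2 * n)
    d2 = np.sum((X[i] - X[j]) ** 2, axis=1)
    d2 = d2[d2 > 0]
    if d2.size == 0:
        raise ValueError("degenerate geometry: all points identical")
    inv = 1.0 / d2
    lo, hi = np.quantile(inv, [quantile_lo, quantile_hi])
    if midpoint:
        return float(0.5 * (lo + hi))
    return float(rng.uniform(lo, hi))


@dataclass
class ClassifierModel:
    """Trained SVM state, self-contained for serialization.

    Prediction is computed directly from the stored support vectors as
    sum_i alpha_i k(sv_i, x) + b > 0 -> RFN, which reproduces the fitted
    sklearn decision function exactly.
    """

    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    sigma: float
    cost: float
    class_weights: tuple[float, float]
    conditioning: ConditioningStats | None
    feature_names: tuple[str, ...]
    version: str = "icsift-0.1.0"

    @property
    def n_support(self) -> int:
        return int(self.support_vectors.shape[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = kernel_matrix(self.support_vectors, np.atleast_2d(X), self.sigma)
        return self.dual_coefficients @ K + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict 1 (RFN) where the decision function is positive, else 0."""
        return (self.decision_function(X) > 0).astype(int)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.predict(X) == 1, RFN, ART)

    def to_dict(self) -> dict:
        cond = None
        if self.conditioning is not None:
            cond = {
                "names": list(self.conditioning.names),
                "mean": self.conditioning.mean.tolist(),
                "sd": self.conditioning.sd.tolist(),
            }
        return {
            "version": self.version,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefficients": self.dual_coefficients.tolist(),
            "bias": self.bias,
            "sigma": self.sigma,
            "cost": self.cost,
            "class_weights": list(self.class_weights),
            "conditioning": cond,
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassifierModel":
        cond = payload.get("conditioning")
        conditioning = None
        if cond is not None:
            conditioning = ConditioningStats(
                tuple(cond["names"]), np.asarray(cond["mean"]), np.asarray(cond["sd"])
            )
        return cls(
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coefficients=np.asarray(payload["dual_coefficients"], dtype=float),
            bias=float(payload["bias"]),
            sigma=float(payload["sigma"]),
            cost=float(payload["cost"]),
            class_weights=tuple(payload["class_weights"]),
            conditioning=conditioning,
            feature_names=tuple(payload["feature_names"]),
            version=str(payload.get("version", "unknown")),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ClassifierModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train(
    features: np.ndarray,
    labels: np.ndarray,
    cost: float = 100.0,
    sigma: float | None = None,
    class_weights: tuple[float, float] = DEFAULT_CLASS_WEIGHTS,
    seed: int | None = None,
    conditioning: ConditioningStats | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ClassifierModel:
    """Fit the soft-margin RBF SVM on conditioned features.

    ``labels`` are 1 for RFN and 0 for ART (string labels are accepted).
    ``sigma=None`` invokes the quantile heuristic with the given seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training set")
    if sigma is None:
        sigma = estimate_sigma(X, seed=seed)
    w_rfn, w_art = class_weights
    svc = SVC(C=cost, kernel="rbf", gamma=sigma, class_weight={1: w_rfn, 0: w_art})
    svc.fit(X, y)
    return ClassifierModel(
        support_vectors=np.asarray(svc.support_vectors_, dtype=float),
        dual_coefficients=np.asarray(svc.dual_coef_[0], dtype=float),
        bias=float(svc.intercept_[0]),
        sigma=float(sigma),
        cost=float(cost),
        class_weights=(float(w_rfn), float(w_art)),
        conditioning=conditioning,
        feature_names=tuple(feature_names),
    )


def _as_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        return np.asarray([1 if str(v) == RFN else 0 for v in labels], dtype=int)
    return labels.astype(int)


@dataclass(frozen=True)
class GridSearchSpec:
    """Exhaustive (C, sigma) grid: bounds, steps and CV fold count."""

    c_range: tuple[float, float] = (10.0, 1000.0)
    c_step: float = 10.0
    sigma_range: tuple[float, float] = (0.1, 1.0)
    sigma_step: float = 0.1
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.c_step <= 0 or self.sigma_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.c_range[1] < self.c_range[0] or self.sigma_range[1] < self.sigma_range[0]:
            raise ValueError("grid ranges must be non-empty")

    def c_values(self) -> np.ndarray:
        lo, hi = self.c_range
        return np.round(np.arange(lo, hi + 1e-9, self.c_step), 10)

    def sigma_values(self) -> np.ndarray:
        lo, hi = self.sigma_range
        return np.round(np.arange(lo, hi + 1e-9, self.sigma_step), 10)

    @property
    def n_points(self) -> int:
        return self.c_values().size * self.sigma_values().size


@dataclass
class GridSearchResult:
    best_c: float
    best_sigma: float
    table: pd.DataFrame = field(repr=False)
    sensitivity_constraint_met: bool = True


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    spec: GridSearchSpec | None = None,
    seed: int = 0,
    class_weights: tuple[float, float] = DEFAULT_CLASS_WEIGHTS,
) -> GridSearchResult:
    """Evaluate every (C, sigma) grid node by stratified cross-validation.

    Returns the node maximizing mean accuracy among nodes whose mean
    cross-validated sensitivity is 1; ties are broken by smaller C, then
    smaller sigma.  If no node attains sensitivity 1, accuracy alone decides
    (with a warning and a flag on the result).
    """
    spec = spec or GridSearchSpec()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _as_binary(labels)
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    w_rfn, w_art = class_weights
    rows = []
    for sigma in spec.sigma_values():
        for c in spec.c_values():
            accs, sens = [], []
            for tr_idx, val_idx in folds:
                svc = SVC(C=c, kernel="rbf", gamma=sigma, class_weight={1: w_rfn, 0: w_art})
                svc.fit(X[tr_idx], y[tr_idx])
                pred = svc.predict(X[val_idx])
                truth = y[val_idx]
                accs.append(float(np.mean(pred == truth)))
                pos = truth == 1
                sens.append(float(np.mean(pred[pos] == 1)) if pos.any() else np.nan)
            rows.append(
                {
                    "C": float(c),
                    "sigma": float(sigma),
                    "mean_accuracy": float(np.mean(accs)),
                    "mean_sensitivity": float(np.nanmean(sens)),
                }
            )
    table = pd.DataFrame(rows)
    feasible = table[table["mean_sensitivity"] >= 1.0 - 1e-12]
    constraint_met = not feasible.empty
    if not constraint_met:
        warnings.warn("no grid point achieved sensitivity 1; maximizing accuracy alone")
        feasible = table
    best_acc = feasible["mean_accuracy"].max()
    candidates = feasible[feasible["mean_accuracy"] >= best_acc - 1e-12]
    best = candidates.sort_values(["C", "sigma"]).iloc[0]
    return GridSearchResult(
        best_c=float(best["C"]),
        best_sigma=float(best["sigma"]),
        table=table,
        sensitivity_constraint_met=constraint_met,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with RFN as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassCounts:
    """Per-class component counts of one classified decomposition."""

    n_rfn: int
    n_art: int

    @property
    def nic(self) -> int:
        return self.n_rfn + self.n_art


@dataclass(frozen=True)
class ClassificationMetrics:
    """Precision, sensitivity, specificity, accuracy; NaN where undefined."""

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    undefined: tuple[str, ...] = ()


def metrics(
    predicted: LabelTable, truth: LabelTable
) -> tuple[ConfusionCounts, ClassificationMetrics]:
    """Compare predicted against reference labels (RFN positive).

    Undefined ratios (zero denominators) are reported as NaN and named in
    ``undefined`` rather than silently coerced to 0.
    """
    if set(predicted.ids()) != set(truth.ids()):
        raise ValueError("predicted and truth tables must cover the same component ids")
    tp = fp = tn = fn = 0
    for comp_id in truth.ids():
        t, p = truth[comp_id], predicted[comp_id]
        if t == RFN and p == RFN:
            tp += 1
        elif t == ART and p == RFN:
            fp += 1
        elif t == ART and p == ART:
            tn += 1
        else:
            fn += 1
    counts = ConfusionCounts(tp, fp, tn, fn)

    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    m = ClassificationMetrics(
        precision=ratio(tp, tp + fp, "precision"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        accuracy=ratio(tp + tn, counts.total, "accuracy"),
        undefined=tuple(undefined),
    )
    return counts, m


def classify_set(
    model: ClassifierModel,
    ica_set: ICASet,
    gm: BinaryMask,
    spec: ThresholdSpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    connectivity: int = 6,
) -> tuple[LabelTable, ClassCounts]:
    """Extract, condition and classify every component of a decomposition.

    Components with no retained suprathreshold cluster cannot be functional
    networks under the filtering rule and are force-labeled ART.
    """
    if model.conditioning is None:
        raise ValueError("model carries no conditioning statistics; cannot classify raw sets")
    if tuple(model.feature_names) != tuple(model.conditioning.names):
        raise ValueError("model feature names do not match its conditioning statistics")
    if ica_set.nic == 0:
        return LabelTable({}), ClassCounts(0, 0)
    table = extract_feature_table(ica_set, gm, spec, band, connectivity)
    X = model.conditioning.transform(table[list(model.feature_names)].to_numpy(dtype=float))
    pred = model.predict(X)
    degenerate = table["degenerate"].to_numpy(dtype=bool)
    pred[degenerate] = 0
    entries = {int(cid): (RFN if p == 1 else ART) for cid, p in zip(table.index, pred)}
    labels = LabelTable(entries)
    return labels, ClassCounts(labels.count(RFN), labels.count(ART))


def fit_conditioned(
    raw_features: pd.DataFrame,
    labels: np.ndarray,
    **train_kwargs,
) -> ClassifierModel:
    """Convenience: fit conditioning on raw features, then train on them."""
    cols = [c for c in raw_features.columns if c in FEATURE_NAMES]
    mat = raw_features[cols].to_numpy(dtype=float)
    cond = fit_conditioning(mat)
    return train(
        cond.transform(mat),
        labels,
        conditioning=cond,
        feature_names=tuple(cols),
        **train_kwargs,
    )


def artifact_overlap_rate(n_art_manual: int, n_false_negative: int) -> float:
    """Percent of manually identified artifact components also caught
    automatically: 100 (N - FN) / N."""
    if n_art_manual <= 0:
        raise ValueError("n_art_manual must be positive")
    if not 0 <= n_false_negative <= n_art_manual:
        raise ValueError("false negatives must be between 0 and n_art_manual")
    return 100.0 * (n_art_manual - n_false_negative) / n_art_manual
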