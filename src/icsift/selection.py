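"""F-score feature ranking, iterative threshold-and-validate reduction, and
binomial-GLM explanatory-power testing.

The selection loop mirrors how a practitioner prunes a feature pool before
fitting a small-sample SVM: rank features by their two-class Fisher ratio
(F-score), sweep an ascending list of score thresholds dropping weak
features, and at each step estimate validation accuracy over repeated random
train/validation splits.  The sweep stops when accuracy drops noticeably;
the kept set is the smallest one whose mean validation accuracy stays within
a tolerance of the best observed.  Explanatory power of individual features
is assessed with a logistic (binomial-variance, logit-link) GLM, and models
of different sizes are compared by AIC and relative AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split

__all__ = [
    "FScoreTable",
    "SelectionResult",
    "GlmReport",
    "f_score",
    "f_score_table",
    "select_features",
    "glm_explanatory",
    "relative_aic",
]


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class Fisher-ratio F-score of one feature.

    F = [(m_pos - m)^2 + (m_neg - m)^2] / (s2_pos + s2_neg), with m the
    pooled mean and s2 the within-class sample variances.  Larger means the
    feature separates the classes more.  Invariant under affine rescaling of
    the feature and under swapping the class labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    pos, neg = values[labels], values[~labels]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 samples in each class")
    m = values.mean()
    num = (pos.mean() - m) ** 2 + (neg.mean() - m) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if den == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero within-class variance in both classes; F-score is infinite")
        return float("inf")
    return float(num / den)


@dataclass
class FScoreTable:
    """Per-feature F-scores with a descending ranking."""

    scores: dict[str, float]
    ranking: list[str]

    def above(self, threshold: float) -> list[str]:
        return [name for name in self.ranking if self.scores[name] >= threshold]


def f_score_table(features: pd.DataFrame, labels: np.ndarray) -> FScoreTable:
    scores = {str(col): f_score(features[col].to_numpy(), labels) for col in features.columns}
    ranking = sorted(scores, key=lambda name: -scores[name])
    return FScoreTable(scores, ranking)


@dataclass
class SelectionResult:
    kept_features: list[str]
    threshold_path: list[tuple[float, list[str], float]]  # (threshold, kept, mean accuracy)
    n_repeats: int
    seed: int
    scores: FScoreTable | None = field(default=None, repr=False)


def _default_trainer():
    # imported lazily to keep selection importable without the classifier
    from .svm import estimate_sigma, train

    def trainer(X_train, y_train, X_val, seed):
        sigma = estimate_sigma(X_train, seed=seed)
        model = train(X_train, y_train, cost=100.0, sigma=sigma)
        return model.predict(X_val)

    return trainer


def select_features(
    features: pd.DataFrame,
    labels: np.ndarray,
    thresholds: list[float],
    n_repeats: int = 50,
    holdout_frac: float = 0.3,
    seed: int = 0,
    trainer=None,
    stop_tol: float = 0.02,
    keep_tol: float = 0.02,
) -> SelectionResult:
    """Iterative F-score threshold sweep with repeated-split validation.

    ``trainer(X_train, y_train, X_val, seed) -> predicted labels`` trains the
    classifier used to score each candidate feature set; the default is the
    RBF-SVM with cost 100 and the sigma-quantile heuristic.  The sweep stops
    early once mean validation accuracy falls more than ``stop_tol`` below
    the best mean seen so far, or when a threshold would drop every feature.
    """
    labels = np.asarray(labels).astype(int)
    if len(features) < 10:
        raise ValueError("need at least 10 samples for selection")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    trainer = trainer or _default_trainer()
    table = f_score_table(features, labels)
    rng = np.random.default_rng(seed)
    path: list[tuple[float, list[str], float]] = []
    best = -np.inf
    for thr in thresholds:
        kept = table.above(thr)
        if not kept:
            break
        X = features[kept].to_numpy(dtype=float)
        accs = np.empty(n_repeats)
        for rep in range(n_repeats):
            split_seed = int(rng.integers(2**31 - 1))
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, labels, test_size=holdout_frac, stratify=labels, random_state=split_seed
            )
            pred = np.asarray(trainer(X_tr, y_tr, X_val, split_seed))
            accs[rep] = float(np.mean(pred == y_val))
        mean_acc = float(accs.mean())
        path.append((float(thr), kept, mean_acc))
        best = max(best, mean_acc)
        if mean_acc < best - stop_tol:
            break
    if not path:
        raise ValueError("the first threshold already dropped every feature")
    best_acc = max(acc for _, _, acc in path)
    eligible = [(len(kept), -acc, kept) for _, kept, acc in path if acc >= best_acc - keep_tol]
    eligible.sort(key=lambda item: (item[0], item[1]))
    kept_features = eligible[0][2]
    return SelectionResult(kept_features, path, n_repeats, seed, scores=table)


@dataclass
class GlmReport:
    """Per-coefficient Wald statistics and AIC of a logistic GLM fit."""

    table: pd.DataFrame  # columns: estimate, t_value, p_value; index: term names
    aic: float
    separation_warning: bool = False


def glm_explanatory(features: pd.DataFrame | np.ndarray, labels: np.ndarray) -> GlmReport:
    """Fit labels ~ features with binomial variance and logit link.

    Reports per-coefficient Wald z statistics ("t-values") and two-sided
    p-values plus the model AIC (2k - 2 loglik).  Perfect separation is
    reported via a flag; estimates then sit near the optimizer's boundary.
    """
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        names = [str(c) for c in features.columns]
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    design = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
        for w in caught:
            if "separa" in str(w.message).lower() or "converge" in str(w.message).lower():
                separation = True
    if np.any(np.abs(result.params) > 1e2):
        separation = True
    table = pd.DataFrame(
        {
            "estimate": result.params,
            "t_value": result.tvalues,
            "p_value": result.pvalues,
        },
        index=["intercept"] + names,
    )
    return GlmReport(table=table, aic=float(result.aic), separation_warning=separation)


def relative_aic(aic_a: float, aic_b: float) -> float:
    """Relative AIC exp((AIC_a - AIC_b) / 2).

    Values below 1 favour model a: the ratio estimates how much more likely
    model a is to minimise information loss than model b.
    """
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise ValueError("AIC values must be finite")
    return float(np.exp((aic_a - aic_b) / 2.0))
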