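"""Penalized logistic regression linking TF-Gene score changes to expression.

One model is fit per condition pair and assay: the features are per-gene
log2 ratios of TF-Gene scores between the two conditions, the label is
whether the gene's expression went up or down. The absolute fitted
coefficient |eta(t)| of each TF then enters the combined TF-target-gene
score as regression evidence that the TF discriminates up- from
down-regulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["RegressionResult", "build_features", "fit_logistic"]

DEFAULT_PENALTY_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)  # inverse strength C


@dataclass
class RegressionResult:
    pairing: str
    assay: str
    coefficients: dict[str, float]  # tf -> eta(t)
    hyperparameter: float  # selected C (inverse penalty strength)
    cv_accuracy: float
    seed: int

    def abs_eta(self, tf: str) -> float:
        return abs(self.coefficients.get(tf, 0.0))


def build_features(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    log2fc: pd.Series,
    eps: float = 1e-6,
    min_per_class: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x TF feature table and up/down labels for one condition pair.

    feature(g, t) = log2((a_B(g,t) + eps) / (a_A(g,t) + eps)), standardized
    per TF to zero mean and unit variance (constant columns stay zero).
    label(g) = 1 if log2fc(g) > 0 else 0; genes with log2fc exactly 0 are
    dropped as uninformative.
    """
    if not scores_a.columns.equals(scores_b.columns) or not scores_a.index.equals(
        scores_b.index
    ):
        raise ValueError("score matrices must share gene and TF universes")
    genes = scores_a.index.intersection(log2fc.index)
    fc = log2fc.loc[genes]
    keep = fc != 0
    genes = genes[keep]
    fc = fc[keep]

    features = np.log2(
        (scores_b.loc[genes] + eps) / (scores_a.loc[genes] + eps)
    )
    labels = (fc > 0).astype(int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if min(n_pos, n_neg) < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} genes per class, got up={n_pos} down={n_neg}"
        )
    mu = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (features - mu) / sd, labels


def fit_logistic(
    features: pd.DataFrame,
    labels: pd.Series,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    folds: int = 5,
    seed: int = 42,
    pairing: str = "",
    assay: str = "",
    l1_ratio: float = 0.5,
) -> RegressionResult:
    """Elastic-net logistic fit with stratified cross-validated penalty choice.

    The inverse penalty strength C is chosen from ``penalty_grid`` by
    maximizing mean held-out accuracy over ``folds`` stratified folds,
    then the model is refit on all data; accuracy ties keep the stronger
    penalty. The L1 component zeroes the coefficients of TFs whose score
    changes carry no information about the labels, so uninformative TFs
    drop out of the downstream combined score entirely instead of
    entering it with a noise-scaled weight. Deterministic given the seed.
    """
    y = labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = features.to_numpy()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def make(c: float) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=l1_ratio,
            C=c,
            solver="saga",
            max_iter=20_000,
            tol=1e-6,
            random_state=seed,
        )

    grid = sorted(penalty_grid)  # ascending C = strongest penalty first
    fold_accs = {
        c: cross_val_score(make(c), X, y, cv=cv, scoring="accuracy") for c in grid
    }
    means = {c: fold_accs[c].mean() for c in grid}
    best_c = max(grid, key=lambda c: means[c])
    # one-standard-error rule: the strongest penalty whose held-out accuracy
    # is within one SE of the best keeps model selection from chasing CV
    # noise at small n
    se = fold_accs[best_c].std(ddof=1) / np.sqrt(folds)
    chosen = next(c for c in grid if means[c] >= means[best_c] - se)
    best_acc = means[chosen]
    final = make(chosen).fit(X, y)
    coefs = dict(zip(features.columns, final.coef_[0].astype(float)))
    return RegressionResult(
        pairing=pairing,
        assay=assay,
        coefficients=coefs,
        hyperparameter=float(chosen),
        cv_accuracy=float(best_acc),
        seed=seed,
    )
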