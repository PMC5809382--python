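"""Linear discriminant analysis of reference-species shape scores.

Two-class LDA with a pooled within-group covariance, class priors
proportional to group sizes (or uniform), leave-one-out
cross-validation, and standardized discriminant coefficients that rank
the shape PCs by their contribution to species separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LdaError(ValueError):
    """Raised for inputs on which a 2-class LDA is undefined."""


@dataclass
class LdaModel:
    """Fisher discriminant for two groups on PC scores."""

    groups: list[str]
    priors: np.ndarray = field(repr=False)
    group_means: np.ndarray = field(repr=False)  # (2, p)
    pooled_cov: np.ndarray = field(repr=False)  # (p, p)
    coef: np.ndarray = field(repr=False)  # raw discriminant direction (p,)
    intercept: float = 0.0
    feature_names: list[str] = field(default_factory=list)

    def decision_values(self, scores: np.ndarray) -> np.ndarray:
        """Log posterior-odds of group 1 over group 0 per specimen."""
        X = np.atleast_2d(np.asarray(scores, dtype=float))
        return X @ self.coef + self.intercept

    def classify(self, scores: np.ndarray) -> np.ndarray:
        """Maximum-posterior class labels."""
        dv = self.decision_values(scores)
        return np.where(dv > 0, self.groups[1], self.groups[0])

    def discriminant_scores(self, scores: np.ndarray) -> np.ndarray:
        """Projection of specimens onto the discriminant axis."""
        return np.atleast_2d(np.asarray(scores, dtype=float)) @ self.coef


def _validate(scores: np.ndarray, labels: np.ndarray, min_per_group: int):
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise LdaError("scores must be (n, p) with one label per row")
    groups, inverse = np.unique(y, return_inverse=True)
    if len(groups) != 2:
        raise LdaError(f"exactly 2 groups required, got {len(groups)}")
    counts = np.bincount(inverse)
    if np.any(counts < min_per_group):
        raise LdaError(
            f"each group needs >= {min_per_group} specimens, got {counts.tolist()}"
        )
    return X, [str(g) for g in groups], inverse, counts


def fit_lda(
    scores: np.ndarray,
    labels: np.ndarray,
    priors: str = "proportional",
    feature_names: list[str] | None = None,
) -> LdaModel:
    """Fit a two-class LDA with pooled within-group covariance.

    Classification is by maximum posterior under shared-covariance
    Gaussians with the stated priors (``"proportional"`` to group sizes
    or ``"uniform"``).
    """
    if priors not in ("proportional", "uniform"):
        raise LdaError(f"unknown priors: {priors!r}")
    X, groups, inverse, counts = _validate(scores, labels, 3)
    n, p = X.shape
    means = np.vstack([X[inverse == g].mean(axis=0) for g in range(2)])
    S = np.zeros((p, p))
    for g in range(2):
        Xg = X[inverse == g] - means[g]
        S += Xg.T @ Xg
    pooled = S / (n - 2)
    try:
        cinv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise LdaError("singular pooled covariance; retain fewer PCs") from exc
    if np.linalg.cond(pooled) > 1e12:
        raise LdaError("near-singular pooled covariance; retain fewer PCs")
    pr = counts / n if priors == "proportional" else np.full(2, 0.5)
    coef = cinv @ (means[1] - means[0])
    intercept = float(
        -0.5 * (means[1] + means[0]) @ coef + np.log(pr[1] / pr[0])
    )
    return LdaModel(
        groups=groups,
        priors=pr,
        group_means=means,
        pooled_cov=pooled,
        coef=coef,
        intercept=intercept,
        feature_names=list(feature_names or [f"PC{i + 1}" for i in range(p)]),
    )


@dataclass
class CvReport:
    """Leave-one-out classification summary."""

    groups: list[str]
    confusion: np.ndarray = field(repr=False)  # rows true, cols predicted
    per_class_pct: np.ndarray = field(repr=False)
    overall_pct: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=[f"true_{g}" for g in self.groups],
            columns=[f"pred_{g}" for g in self.groups],
        )


def loocv_classify(
    scores: np.ndarray,
    labels: np.ndarray,
    priors: str = "proportional",
) -> CvReport:
    """Leave-one-out cross-validated classification.

    Each specimen is classified by an LDA fitted on all other
    specimens; classes must keep >= 3 members in every fold.
    """
    X, groups, inverse, counts = _validate(scores, labels, 4)
    n = len(X)
    confusion = np.zeros((2, 2), dtype=int)
    y = np.asarray(labels).astype(str)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_lda(X[mask], y[mask], priors=priors)
        pred = model.classify(X[i])[0]
        confusion[inverse[i], model.groups.index(pred)] += 1
    per_class = 100.0 * np.diag(confusion) / counts
    overall = 100.0 * np.trace(confusion) / n
    return CvReport(groups, confusion, per_class, float(overall))


def standardized_coefficients(
    model: LdaModel,
    cumulative_cutoff: float = 0.7,
    top_k: int = 4,
) -> pd.DataFrame:
    """Standardized discriminant coefficients, ranked by magnitude.

    Raw coefficients are multiplied by the pooled within-group SD of
    each PC, making them comparable across PCs.  ``species_pc`` marks
    the smallest leading set whose absolute standardized coefficients
    reach ``cumulative_cutoff`` of the total contribution, extended to
    at least ``top_k`` PCs.
    """
    sd = np.sqrt(np.diag(model.pooled_cov))
    std_coef = model.coef * sd
    order = np.argsort(-np.abs(std_coef))
    contrib = np.abs(std_coef[order]) / np.abs(std_coef).sum()
    cum = np.cumsum(contrib)
    n_select = max(int(np.searchsorted(cum, cumulative_cutoff) + 1), top_k)
    n_select = min(n_select, len(std_coef))
    out = pd.DataFrame(
        {
            "feature": [model.feature_names[i] for i in order],
            "raw_coef": model.coef[order],
            "std_coef": std_coef[order],
            "abs_contribution": contrib,
            "cumulative_contribution": cum,
        }
    )
    out["species_pc"] = np.arange(len(out)) < n_select
    return out
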