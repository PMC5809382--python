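"""PCA morphospace over combined-view Fourier coefficients.

The specimen-by-coefficient matrix is mean-centred and decomposed by
SVD; principal component scores are the new shape variables.  Because
every point of the morphospace is a coefficient vector, shapes can be
reconstructed anywhere in it — in particular at ``mean ± k·SD`` along a
single component, which is how individual shape features are visualised.
Wilks'-lambda MANOVA tests whether site of origin or shell length move
specimens in the space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .efa import EFACoefficients, NormalizationRecord, ShapeMatrix, efa_inverse
from .outline_io import Outline


@dataclass
class MorphospaceModel:
    """Fitted PCA: mean vector, orthonormal loadings, eigenvalues, scores."""

    specimen_ids: list[str]
    mean: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)  # (n_features, n_pcs)
    eigenvalues: np.ndarray = field(repr=False)
    pct_variance: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)  # (n_specimens, n_pcs)
    columns: list[str] = field(default_factory=list, repr=False)

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def score_sd(self, pc_index: int) -> float:
        return float(self.scores[:, pc_index].std(ddof=1))


def fit_pca(matrix: ShapeMatrix) -> MorphospaceModel:
    """Column-mean-centred SVD of the shape matrix.

    Eigenvalues are the sample covariance eigenvalues (ddof 1); the
    columns are deliberately *not* standardised first, so the PCA is on
    the covariance of the raw normalized coefficients.  Loading signs
    follow the convention that each loading's largest-magnitude element
    is positive.
    """
    X = matrix.X
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("all specimens identical: no shape variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    # sign convention: largest |element| of each loading positive
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    pct = 100.0 * eigvals / eigvals.sum()
    return MorphospaceModel(
        specimen_ids=list(matrix.specimen_ids),
        mean=mean,
        loadings=Vt.T,
        eigenvalues=eigvals,
        pct_variance=pct,
        scores=scores,
        columns=list(matrix.columns),
    )


def coefficients_from_vector(
    vec: np.ndarray, n_harmonics: int
) -> tuple[EFACoefficients, EFACoefficients]:
    """Split a combined feature vector back into per-view coefficients."""
    vec = np.asarray(vec, dtype=float)
    per_view = 4 * n_harmonics
    if vec.size != 2 * per_view:
        raise ValueError(
            f"vector length {vec.size} does not match 2 views x {n_harmonics} harmonics"
        )
    lat = EFACoefficients(
        "lateral",
        vec[:per_view].reshape(n_harmonics, 4),
        normalization=NormalizationRecord(normalized=True),
    )
    ven = EFACoefficients(
        "ventral",
        vec[per_view:].reshape(n_harmonics, 4),
        normalization=NormalizationRecord(normalized=True),
    )
    return lat, ven


def _self_intersects(outline: Outline) -> bool:
    """Segment-pair orientation sweep for self-intersection of the polygon."""
    p = outline.closed()
    a, b = p[:-1], p[1:]
    k = len(a)
    i, j = np.triu_indices(k, k=2)
    adjacent = (i == 0) & (j == k - 1)
    i, j = i[~adjacent], j[~adjacent]

    def cross(o, u, v):
        return (u[:, 0] - o[:, 0]) * (v[:, 1] - o[:, 1]) - (u[:, 1] - o[:, 1]) * (
            v[:, 0] - o[:, 0]
        )

    d1 = cross(a[i], b[i], a[j])
    d2 = cross(a[i], b[i], b[j])
    d3 = cross(a[j], b[j], a[i])
    d4 = cross(a[j], b[j], b[i])
    return bool(np.any((d1 * d2 < 0) & (d3 * d4 < 0)))


def reconstruct_at(
    model: MorphospaceModel,
    pc_index: int,
    k_sd: float,
    n_harmonics: int,
    n_points: int = 256,
) -> tuple[Outline, Outline]:
    """Reconstruct the outline pair at ``mean + k_sd * SD`` along one PC.

    Self-intersecting reconstructions (possible far outside the data
    cloud) trigger a warning but are still returned.
    """
    if not np.isfinite(k_sd):
        raise ValueError("k_sd must be finite")
    if not 0 <= pc_index < model.n_pcs:
        raise ValueError(f"pc_index {pc_index} outside retained PCs")
    vec = model.mean + k_sd * model.score_sd(pc_index) * model.loadings[:, pc_index]
    lat, ven = coefficients_from_vector(vec, n_harmonics)
    label = f"PC{pc_index + 1}{k_sd:+g}SD"
    out = (
        efa_inverse(lat, n_points, specimen_id=label),
        efa_inverse(ven, n_points, specimen_id=label),
    )
    for o in out:
        if _self_intersects(o):
            warnings.warn(
                f"reconstruction {label}/{o.view} self-intersects", stacklevel=2
            )
    return out


def project(model: MorphospaceModel, vec: np.ndarray) -> np.ndarray:
    """Project a coefficient vector into the morphospace (PC scores)."""
    return (np.asarray(vec, dtype=float) - model.mean) @ model.loadings


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ManovaResult:
    """Wilks' lambda with Rao's F approximation for one predictor."""

    predictor: str
    wilks_lambda: float
    approx_f: float
    df1: float
    df2: float
    p_value: float


def manova_wilks(
    scores: np.ndarray,
    predictor: np.ndarray,
    predictor_name: str = "predictor",
) -> ManovaResult:
    """Wilks' lambda MANOVA of PC scores on one predictor.

    A categorical predictor gives the group-means model (one-way
    MANOVA); a numeric predictor gives a multivariate regression on the
    covariate.  ``lambda = det(E) / det(E + H)`` with Rao's F
    approximation and its usual degrees of freedom.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("scores must be a 2-D array with >= 1 column")
    n, p = Y.shape
    predictor = np.asarray(predictor)
    numeric = np.issubdtype(predictor.dtype, np.number)

    grand = Y.mean(axis=0)
    Yc = Y - grand
    if numeric:
        x = predictor.astype(float)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            raise ValueError("constant numeric predictor")
        beta = (xc @ Yc) / sxx
        H = sxx * np.outer(beta, beta)
        E = Yc.T @ Yc - H
        q = 1  # hypothesis df
    else:
        levels, inverse = np.unique(predictor, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("categorical predictor needs >= 2 levels")
        counts = np.bincount(inverse)
        if np.any(counts < 2):
            small = levels[counts < 2]
            raise ValueError(f"groups with < 2 specimens: {list(small)}")
        E = np.zeros((p, p))
        H = np.zeros((p, p))
        for g in range(len(levels)):
            Yg = Y[inverse == g]
            mg = Yg.mean(axis=0)
            E += (Yg - mg).T @ (Yg - mg)
            H += len(Yg) * np.outer(mg - grand, mg - grand)
        q = len(levels) - 1

    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular error matrix in MANOVA; retain fewer PCs")
    lam = float(np.exp(logdet_e - logdet_t))

    # Rao's F approximation
    ve = n - 1 - q
    m = ve + q - 0.5 * (p + q + 1)
    if p**2 + q**2 - 5 > 0:
        s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        s = 1.0
    df1 = p * q
    df2 = m * s - 0.5 * (p * q - 2)
    lam_s = lam ** (1.0 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return ManovaResult(predictor_name, lam, float(f), float(df1), float(df2), pval)
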