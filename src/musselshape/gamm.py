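"""Stacked multi-PC additive mixed model of shape scores.

The response is the long ("stacked") table of standardized PC scores:
one row per specimen per shape PC.  The mean structure combines, for
each PC stratum ``j``, an intercept, a linear shell-length term and a
cubic-regression-spline smooth of each environmental covariate::

    score_ijk = f_T(temp_i) x PC_j + f_S(sal_i) x PC_j + f_C(chla_i) x PC_j
                + length_ik x PC_j + PC_j + site_i + eps_ijk
    site_i ~ N(0, sigma2_site)
    sd(eps_ijk) = sigma * exp(delta_j * v_i)        (exponential structure)

with ``v`` a chosen variance covariate (temperature or chl-a) and one
``delta_j`` per PC stratum.  Estimation profiles the fixed effects and
the residual scale out of the (RE)ML objective and optimises the
remaining variance parameters numerically; the site random intercept
enters through a Woodbury identity, so each likelihood evaluation costs
O(n p^2).

Smooths use a fixed, small basis (default dimension 3, hence 2 degrees
of freedom per smooth after centring), i.e. unpenalized regression
splines with manually chosen flexibility; an optional penalized mode is
not provided — flexibility is controlled by the basis dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

PC_COLUMN = "pc"
RESPONSE = "shape_var"
ID_COLS = ("specimen_id", "site_id")


class GammError(RuntimeError):
    """Raised for invalid model specifications or data."""


class ConvergenceError(GammError):
    """Optimizer failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# data containers


@dataclass
class LongShapeTable:
    """Stacked (specimen, site, PC, score, covariates) records.

    Each PC column of the wide score matrix is standardized to mean 0,
    SD 1 *before* stacking, so strata are comparable and the variance
    parameters refer to a common scale.
    """

    data: pd.DataFrame = field(repr=False)
    covariates: tuple[str, ...] = ("temperature", "salinity", "chla", "length")

    def __post_init__(self) -> None:
        required = set(ID_COLS) | {PC_COLUMN, RESPONSE} | set(self.covariates)
        missing = required - set(self.data.columns)
        if missing:
            raise GammError(f"long table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["specimen_id", PC_COLUMN])
        if dup.any():
            raise GammError("duplicate (specimen, pc) rows in long table")

    @property
    def pc_levels(self) -> list[str]:
        return sorted(self.data[PC_COLUMN].unique(), key=lambda s: (len(s), s))

    @property
    def n_sites(self) -> int:
        return self.data["site_id"].nunique()


def stack_scores(
    scores: np.ndarray,
    specimen_ids: list[str],
    specimens: pd.DataFrame,
    env: pd.DataFrame,
    k_pcs: int = 5,
    standardize: bool = True,
) -> LongShapeTable:
    """Build the stacked long table from wide PC scores.

    ``specimens`` must carry ``specimen_id, site_id, length``; ``env``
    must carry ``site_id, temperature, salinity, chla``.  Each of the
    first ``k_pcs`` score columns is standardized (mean 0, SD 1) before
    stacking.
    """
    scores = np.asarray(scores, dtype=float)
    if k_pcs > scores.shape[1]:
        raise GammError(f"k_pcs={k_pcs} exceeds available PCs ({scores.shape[1]})")
    wide = pd.DataFrame(
        scores[:, :k_pcs], columns=[f"PC{i + 1}" for i in range(k_pcs)]
    )
    wide["specimen_id"] = list(specimen_ids)
    merged = wide.merge(specimens, on="specimen_id", how="left", validate="1:1")
    if merged["site_id"].isna().any():
        missing = merged.loc[merged["site_id"].isna(), "specimen_id"].tolist()
        raise GammError(f"specimens without metadata: {missing}")
    merged = merged.merge(env, on="site_id", how="left", validate="m:1")
    env_cols = ["temperature", "salinity", "chla"]
    if merged[env_cols].isna().any().any():
        bad = sorted(merged.loc[merged[env_cols].isna().any(axis=1), "site_id"].unique())
        raise GammError(f"sites without environment data: {bad}")

    pc_cols = [f"PC{i + 1}" for i in range(k_pcs)]
    if standardize:
        for c in pc_cols:
            sd = merged[c].std(ddof=1)
            if sd == 0:
                raise GammError(f"{c} has zero variance; cannot standardize")
            merged[c] = (merged[c] - merged[c].mean()) / sd
    long = merged.melt(
        id_vars=["specimen_id", "site_id", "length"] + env_cols,
        value_vars=pc_cols,
        var_name=PC_COLUMN,
        value_name=RESPONSE,
    ).reset_index(drop=True)
    return LongShapeTable(long)


# ---------------------------------------------------------------------------
# collinearity screening


def vif(site_covariates: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Variance inflation factors of site covariates.

    ``VIF_c = 1 / (1 - R^2_c)`` from regressing covariate ``c`` on the
    others (with intercept).  Perfect collinearity is reported as an
    infinite VIF rather than raised.
    """
    X = site_covariates.select_dtypes(include=[np.number])
    if X.shape[0] < 3:
        raise GammError("need >= 3 sites for VIF")
    if X.shape[1] < 2:
        raise GammError("need >= 2 covariates for VIF")
    out = []
    for c in X.columns:
        y = X[c].to_numpy(dtype=float)
        others = X.drop(columns=c).to_numpy(dtype=float)
        A = np.column_stack([np.ones(len(y)), others])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        if tss == 0:
            v = np.inf
        else:
            r2 = 1.0 - rss / tss
            v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append((c, v))
    frame = pd.DataFrame(out, columns=["covariate", "vif"])
    frame["collinear"] = frame["vif"] >= threshold
    return frame


@dataclass
class EnviroPCs:
    """PCA of standardized site covariates used as orthogonal predictors."""

    loadings: pd.DataFrame = field(repr=False)  # covariate x enviro-PC
    scores: pd.DataFrame = field(repr=False)  # site x enviro-PC
    pct_variance: np.ndarray = field(repr=False)
    center: pd.Series = field(repr=False)
    scale: pd.Series = field(repr=False)


def env_pca(site_covariates: pd.DataFrame, site_ids: pd.Series | None = None) -> EnviroPCs:
    """PCA on standardized site covariates (``enviro-PC1, 2, ...``).

    Loadings follow the same sign convention as the morphospace PCA:
    the largest-magnitude element of each loading is positive.
    """
    X = site_covariates.select_dtypes(include=[np.number])
    n, p = X.shape
    if n < p:
        raise GammError(f"fewer sites ({n}) than covariates ({p})")
    center = X.mean()
    scale = X.std(ddof=1)
    if (scale == 0).any():
        raise GammError("constant covariate; cannot standardize for PCA")
    Z = ((X - center) / scale).to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    eig = s**2 / max(n - 1, 1)
    pct = 100.0 * eig / eig.sum()
    labels = [f"enviro-PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(Z @ Vt.T, columns=labels)
    if site_ids is not None:
        scores.insert(0, "site_id", list(site_ids))
    return EnviroPCs(
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=labels),
        scores=scores,
        pct_variance=pct,
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# spline basis


def natural_cubic_curvatures(knots: np.ndarray) -> np.ndarray:
    """Matrix F mapping values-at-knots to natural-spline curvatures."""
    k = len(knots)
    h = np.diff(knots)
    if np.any(h <= 0):
        raise GammError("knots must be strictly increasing")
    F = np.zeros((k, k))
    if k > 2:
        B = np.zeros((k - 2, k - 2))
        D = np.zeros((k - 2, k))
        for i in range(1, k - 1):
            r = i - 1
            B[r, r] = (h[i - 1] + h[i]) / 3.0
            if r > 0:
                B[r, r - 1] = h[i - 1] / 6.0
            if r < k - 3:
                B[r, r + 1] = h[i] / 6.0
            D[r, i - 1] = 1.0 / h[i - 1]
            D[r, i] = -1.0 / h[i - 1] - 1.0 / h[i]
            D[r, i + 1] = 1.0 / h[i]
        F[1:-1] = np.linalg.solve(B, D)
    return F


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cardinal natural cubic regression spline basis (mgcv-style "cr").

    Column ``j`` is the natural cubic spline taking value 1 at knot
    ``j`` and 0 at the others, extended linearly outside the knot
    range.  Rows sum to 1 (the basis reproduces constants exactly).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    F = natural_cubic_curvatures(knots)
    h = np.diff(knots)
    xi = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    t0, t1 = knots[xi], knots[xi + 1]
    hi = h[xi]
    xx = np.clip(x, knots[0], knots[-1])
    am = (t1 - xx) / hi
    ap = (xx - t0) / hi
    cm = ((t1 - xx) ** 3 / hi - hi * (t1 - xx)) / 6.0
    cp = ((xx - t0) ** 3 / hi - hi * (xx - t0)) / 6.0
    A = np.zeros((len(x), k))
    rows = np.arange(len(x))
    A[rows, xi] = am
    A[rows, xi + 1] = ap
    basis = A + cm[:, None] * F[xi] + cp[:, None] * F[xi + 1]
    # linear extrapolation beyond the boundary knots
    below = x < knots[0]
    above = x > knots[-1]
    if below.any() or above.any():
        eps = 1e-6 * (knots[-1] - knots[0])
        for mask, edge, sgn in ((below, knots[0], 1.0), (above, knots[-1], -1.0)):
            if not mask.any():
                continue
            b0 = natural_cubic_basis(np.array([edge]), knots)
            b1 = natural_cubic_basis(np.array([edge + sgn * eps]), knots)
            slope = sgn * (b1 - b0) / eps
            basis[mask] = b0 + (x[mask] - edge)[:, None] * slope
    return basis


# ---------------------------------------------------------------------------
# model specification


@dataclass
class FormulaSpec:
    """Mean-structure specification of the stacked model.

    ``smooth_terms`` get a cubic-regression-spline basis of dimension
    ``basis_dim`` per PC stratum; ``linear_terms`` get one slope per PC
    stratum; every PC stratum has its own intercept.
    """

    smooth_terms: tuple[str, ...] = ("temperature", "salinity", "chla")
    linear_terms: tuple[str, ...] = ("length",)
    basis_dim: int = 3


@dataclass
class VarianceStructure:
    """Residual variance model.

    ``identity``: constant residual variance.  ``exponential``:
    ``sd = sigma * exp(delta_j * (v - v_mean))`` with one ``delta_j``
    per PC stratum for variance covariate ``v``.
    """

    kind: str = "identity"
    covariate: str | None = None
    delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "exponential"):
            raise GammError(f"unknown variance structure: {self.kind!r}")
        if self.kind == "exponential" and self.covariate is None:
            raise GammError("exponential variance structure needs a covariate")


@dataclass
class TermBlock:
    term: str
    pc: str
    columns: np.ndarray  # design column indices
    site_level: bool


@dataclass
class GammDesign:
    """Frozen design information, sufficient to rebuild rows for new data."""

    pc_levels: list[str]
    column_names: list[str]
    blocks: list[TermBlock]
    knots: dict[str, np.ndarray]
    centers: dict[str, float]
    formula: FormulaSpec
    covariate_range: dict[str, tuple[float, float]]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        X = np.zeros((n, len(self.column_names)))
        pc = df[PC_COLUMN].to_numpy()
        col = 0
        for j, lev in enumerate(self.pc_levels):
            mask = (pc == lev).astype(float)
            X[:, col] = mask
            col += 1
            for t in self.formula.linear_terms:
                X[:, col] = (df[t].to_numpy(dtype=float) - self.centers[t]) * mask
                col += 1
            for t in self.formula.smooth_terms:
                B = natural_cubic_basis(df[t].to_numpy(dtype=float), self.knots[t])
                B0 = natural_cubic_basis(np.array([self.centers[t]]), self.knots[t])
                Bc = (B - B0)[:, 1:]  # rows sum to 0 after centring: drop one col
                X[:, col : col + Bc.shape[1]] = Bc * mask[:, None]
                col += Bc.shape[1]
        return X


def _build_design(table: LongShapeTable, formula: FormulaSpec) -> GammDesign:
    df = table.data
    pc_levels = table.pc_levels
    knots: dict[str, np.ndarray] = {}
    centers: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for t in formula.smooth_terms + formula.linear_terms:
        x = df[t].to_numpy(dtype=float)
        centers[t] = float(x.mean())
        ranges[t] = (float(x.min()), float(x.max()))
    for t in formula.smooth_terms:
        qs = np.linspace(0.0, 1.0, formula.basis_dim)
        kn = np.quantile(np.unique(df[t].to_numpy(dtype=float)), qs)
        if len(np.unique(kn)) < formula.basis_dim:
            raise GammError(f"covariate {t!r}: too few distinct values for knots")
        knots[t] = kn

    site_level_covs = {
        t
        for t in formula.smooth_terms + formula.linear_terms
        if df.groupby("site_id")[t].nunique().max() == 1
    }
    names: list[str] = []
    blocks: list[TermBlock] = []
    col = 0
    n_basis = formula.basis_dim - 1
    for lev in pc_levels:
        names.append(f"{lev}")
        blocks.append(TermBlock("intercept", lev, np.array([col]), False))
        col += 1
        for t in formula.linear_terms:
            names.append(f"{t}:{lev}")
            blocks.append(TermBlock(t, lev, np.array([col]), t in site_level_covs))
            col += 1
        for t in formula.smooth_terms:
            idx = np.arange(col, col + n_basis)
            names.extend(f"s({t}){i + 1}:{lev}" for i in range(n_basis))
            blocks.append(TermBlock(f"s({t})", lev, idx, t in site_level_covs))
            col += n_basis
    return GammDesign(pc_levels, names, blocks, knots, centers, formula, ranges)


# ---------------------------------------------------------------------------
# (RE)ML engine


@dataclass
class GammFit:
    """A fitted stacked additive mixed model."""

    design: GammDesign
    variance: VarianceStructure
    method: str
    beta: np.ndarray = field(repr=False)
    cov_beta: np.ndarray = field(repr=False)
    sigma2: float = 0.0
    sigma2_site: float = 0.0
    loglik: float = 0.0
    n_obs: int = 0
    n_params: int = 0
    term_table: pd.DataFrame = field(default=None, repr=False)
    table: LongShapeTable = field(default=None, repr=False)
    converged: bool = True
    v_center: float = 0.0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        n, p = self.n_obs, self.n_params
        if n - p - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * p * (p + 1) / (n - p - 1)

    def residual_sd(self, v: np.ndarray, pc: np.ndarray) -> np.ndarray:
        """Fitted residual SD at variance-covariate values per stratum."""
        sd = np.full(len(np.atleast_1d(v)), np.sqrt(self.sigma2))
        if self.variance.kind == "exponential":
            levels = self.design.pc_levels
            dmap = dict(zip(levels, self.variance.delta))
            d = np.array([dmap[p] for p in np.atleast_1d(pc)])
            sd = sd * np.exp(d * (np.atleast_1d(v) - self.v_center))
        return sd


def _profiled_neg2ll(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    site_idx: np.ndarray,
    q: int,
    vc: np.ndarray | None,
    strata_idx: np.ndarray | None,
    n_delta: int,
    method: str,
) -> float:
    n, p = X.shape
    log_psi = theta[0]
    psi = np.exp(log_psi)
    if n_delta:
        delta = theta[1 : 1 + n_delta]
        logw = 2.0 * delta[strata_idx] * vc  # log of variance weights
        wi = np.exp(-logw)
    else:
        logw = None
        wi = np.ones(n)

    Xw = X * wi[:, None]
    XtWX = X.T @ Xw
    xtwy = Xw.T @ y
    U = np.zeros((q, p))
    np.add.at(U, site_idx, Xw)
    uy = np.bincount(site_idx, weights=wi * y, minlength=q)
    ag = np.bincount(site_idx, weights=wi, minlength=q)
    M = 1.0 + psi * ag

    XtVX = XtWX - psi * (U.T @ (U / M[:, None]))
    XtVy = xtwy - psi * (U.T @ (uy / M))
    ytVy = float(y @ (wi * y)) - psi * float(uy @ (uy / M))
    _PENALTY = 1e10  # finite so numeric differentiation stays well defined
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return _PENALTY
    rss = ytVy - float(beta @ XtVy)
    if rss <= 0 or not np.isfinite(rss):
        return _PENALTY
    logdetV0 = float(np.sum(np.log(M)))
    if logw is not None:
        logdetV0 += float(np.sum(logw))
    if method == "ML":
        sigma2 = rss / n
        return n * np.log(2 * np.pi * sigma2) + logdetV0 + n
    sigma2 = rss / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return _PENALTY
    return (n - p) * np.log(2 * np.pi * sigma2) + logdetV0 + logdet_xvx + (n - p)


def fit_gamm(
    table: LongShapeTable,
    formula: FormulaSpec | None = None,
    variance: VarianceStructure | None = None,
    method: str = "REML",
    max_iter: int = 500,
) -> GammFit:
    """Fit the stacked additive mixed model by profiled (RE)ML.

    The site random-intercept ratio ``psi = sigma2_site / sigma2`` and
    (for the exponential structure) the per-PC ``delta`` are optimised
    numerically; fixed effects and the residual scale are profiled out
    in closed form.  Per-term Wald F statistics use the model-based
    coefficient covariance; denominator degrees of freedom follow a
    containment-style rule (site-level terms are tested against
    between-site information).
    """
    formula = formula or FormulaSpec()
    variance = variance or VarianceStructure("identity")
    if method not in ("ML", "REML"):
        raise GammError(f"method must be ML or REML, got {method!r}")
    design = _build_design(table, formula)
    df = table.data
    y = df[RESPONSE].to_numpy(dtype=float)
    X = design.build(df)
    n, p = X.shape
    if n <= p + 1:
        raise GammError(f"too few rows ({n}) for {p} fixed-effect columns")
    sites, site_idx = np.unique(df["site_id"].to_numpy(), return_inverse=True)
    q = len(sites)

    if variance.kind == "exponential":
        v_raw = df[variance.covariate].to_numpy(dtype=float)
        if np.ptp(v_raw) == 0:
            raise GammError(
                f"variance covariate {variance.covariate!r} is constant"
            )
        v_center = float(v_raw.mean())
        vc = v_raw - v_center
        levels = design.pc_levels
        strata_idx = pd.Categorical(
            df[PC_COLUMN], categories=levels
        ).codes.astype(int)
        n_delta = len(levels)
    else:
        vc, strata_idx, n_delta, v_center = None, None, 0, 0.0

    args = (y, X, site_idx, q, vc, strata_idx, n_delta, method)
    x0 = np.concatenate([[np.log(0.1)], np.zeros(n_delta)])
    bounds = [(-16.0, 12.0)] + [(-1.5, 1.5)] * n_delta
    res = optimize.minimize(
        _profiled_neg2ll,
        x0,
        args=args,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter},
    )
    # derivative-free polish; also rescues a failed quasi-Newton run
    res2 = optimize.minimize(
        _profiled_neg2ll,
        res.x if np.all(np.isfinite(res.x)) else x0,
        args=args,
        method="Powell",
        bounds=bounds,
        options={"maxiter": 4 * max_iter, "xtol": 1e-9, "ftol": 1e-11},
    )
    if res2.fun <= res.fun:
        res = res2
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(
            f"variance-parameter optimisation failed: {res.message}", trace=res
        )

    theta = res.x
    psi = float(np.exp(theta[0]))
    delta = theta[1 : 1 + n_delta].copy() if n_delta else None

    # recompute profiled quantities at the optimum
    if n_delta:
        wi = np.exp(-2.0 * delta[strata_idx] * vc)
    else:
        wi = np.ones(n)
    Xw = X * wi[:, None]
    U = np.zeros((q, p))
    np.add.at(U, site_idx, Xw)
    uy = np.bincount(site_idx, weights=wi * y, minlength=q)
    ag = np.bincount(site_idx, weights=wi, minlength=q)
    M = 1.0 + psi * ag
    XtVX = X.T @ Xw - psi * (U.T @ (U / M[:, None]))
    XtVy = Xw.T @ y - psi * (U.T @ (uy / M))
    ytVy = float(y @ (wi * y)) - psi * float(uy @ (uy / M))
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    sigma2 = rss / n if method == "ML" else rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    loglik = -0.5 * _profiled_neg2ll(theta, *args)

    var_out = replace(variance, delta=delta)
    n_params = p + 2 + n_delta  # fixed effects + sigma2 + sigma2_site + deltas

    fit = GammFit(
        design=design,
        variance=var_out,
        method=method,
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        sigma2_site=float(psi * sigma2),
        loglik=float(loglik),
        n_obs=n,
        n_params=n_params,
        table=table,
        converged=bool(res.success),
        v_center=v_center,
    )
    fit.term_table = _term_table(fit, q)
    return fit


def _term_table(fit: GammFit, q: int) -> pd.DataFrame:
    """Wald F per (term, PC) block with containment-style denominator df."""
    n, p = fit.n_obs, len(fit.beta)
    design = fit.design
    n_pc = len(design.pc_levels)
    site_cols_per_pc = sum(
        len(b.columns) for b in design.blocks if b.site_level
    ) // n_pc
    rows = []
    for b in design.blocks:
        if b.term == "intercept":
            continue
        bb = fit.beta[b.columns]
        C = fit.cov_beta[np.ix_(b.columns, b.columns)]
        df1 = len(b.columns)
        F = float(bb @ np.linalg.solve(C, bb)) / df1
        if b.site_level:
            # information about site-level covariates comes from site x PC
            # cell means net of site random intercepts and cell parameters
            df2 = max(n_pc * q - q - n_pc * (1 + site_cols_per_pc), 1)
        else:
            df2 = n - p
        pval = float(stats.f.sf(F, df1, df2))
        rows.append((b.term, b.pc, float(df1), F, df2, pval))
    return pd.DataFrame(rows, columns=["term", "pc", "edf", "F", "den_df", "p"])


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    fits: dict[str, GammFit],
    nesting: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """AICc table plus likelihood-ratio tests for declared nested pairs.

    ``nesting`` lists ``(reduced, full)`` name pairs; both fits must use
    the same estimation method and the same number of observations.
    Random-structure comparisons should use REML fits, fixed-structure
    comparisons ML fits.
    """
    rows = []
    for name, f in fits.items():
        rows.append(
            {
                "model": name,
                "method": f.method,
                "n_params": f.n_params,
                "logLik": f.loglik,
                "AICc": f.aicc,
            }
        )
    out = pd.DataFrame(rows).set_index("model")
    out["dAICc"] = out["AICc"] - out["AICc"].min()
    out["lrt_vs"] = None
    out["lrt_stat"] = np.nan
    out["lrt_df"] = np.nan
    out["lrt_p"] = np.nan
    for reduced, full in nesting or []:
        fr, ff = fits[reduced], fits[full]
        if fr.method != ff.method:
            raise GammError(
                f"LRT across estimation methods ({fr.method} vs {ff.method})"
            )
        if fr.n_obs != ff.n_obs:
            raise GammError("LRT requires fits on identical data")
        df = ff.n_params - fr.n_params
        if df <= 0:
            raise GammError(f"pair ({reduced}, {full}) is not nested (df <= 0)")
        stat = 2.0 * (ff.loglik - fr.loglik)
        out.loc[full, "lrt_vs"] = reduced
        out.loc[full, "lrt_stat"] = stat
        out.loc[full, "lrt_df"] = df
        out.loc[full, "lrt_p"] = float(stats.chi2.sf(max(stat, 0.0), df))
    return out


# ---------------------------------------------------------------------------
# prediction and effect sizes


def predict_with_ci(
    fit: GammFit,
    newdata: pd.DataFrame,
    pc_label: str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Population-level predictions (random intercept at zero) with CI.

    Covariates absent from ``newdata`` are held at their training means.
    Rows outside the observed covariate range are flagged
    ``extrapolated``.
    """
    design = fit.design
    if pc_label not in design.pc_levels:
        raise GammError(
            f"unknown pc_label {pc_label!r}; have {design.pc_levels}"
        )
    df = newdata.copy()
    covs = list(design.formula.smooth_terms) + list(design.formula.linear_terms)
    for t in covs:
        if t not in df.columns:
            df[t] = design.centers[t]
    df[PC_COLUMN] = pc_label
    X = design.build(df)
    mu = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    extrap = np.zeros(len(df), dtype=bool)
    for t in covs:
        lo, hi = design.covariate_range[t]
        x = df[t].to_numpy(dtype=float)
        extrap |= (x < lo) | (x > hi)
    out = df[covs].copy()
    out["fit"] = mu
    out["se"] = se
    out["ci_lower"] = mu - z * se
    out["ci_upper"] = mu + z * se
    out["extrapolated"] = extrap
    return out


@dataclass
class EffectSize:
    """Mean effect of one covariate on one PC, per SD of the covariate."""

    covariate: str
    pc: str
    estimate: float
    ci_lower: float
    ci_upper: float
    significant: bool


def effect_sizes(
    fit: GammFit,
    table: LongShapeTable | None = None,
    level: float = 0.95,
    method: str = "linear_refit",
) -> pd.DataFrame:
    """Mean effect sizes of standardized covariates per PC with CIs.

    ``linear_refit`` (default): every smooth is replaced by a linear
    term in the standardized covariate and the model is refitted; the
    effect size is that slope (response units per covariate SD).
    ``derivative``: the average first derivative of each fitted smooth
    over the data, multiplied by the covariate SD (no refit).  An effect
    is flagged significant when its CI excludes zero.
    """
    table = table or fit.table
    if table is None:
        raise GammError("effect_sizes needs the fitted table")
    df = table.data
    z = stats.norm.ppf(0.5 + level / 2.0)
    covs = list(fit.design.formula.smooth_terms) + list(
        fit.design.formula.linear_terms
    )
    sds = {t: float(df[t].std(ddof=1)) for t in covs}

    rows: list[EffectSize] = []
    if method == "linear_refit":
        lin_formula = FormulaSpec(
            smooth_terms=(),
            linear_terms=tuple(covs),
            basis_dim=fit.design.formula.basis_dim,
        )
        refit = fit_gamm(table, lin_formula, fit.variance, fit.method)
        if not refit.converged:
            raise ConvergenceError("linear refit for effect sizes did not converge")
        for b in refit.design.blocks:
            if b.term == "intercept":
                continue
            est = float(refit.beta[b.columns[0]]) * sds[b.term]
            se = float(np.sqrt(refit.cov_beta[b.columns[0], b.columns[0]])) * sds[
                b.term
            ]
            rows.append(
                EffectSize(
                    b.term, b.pc, est, est - z * se, est + z * se,
                    bool(est - z * se > 0 or est + z * se < 0),
                )
            )
    elif method == "derivative":
        design = fit.design
        for b in design.blocks:
            if b.term == "intercept":
                continue
            name = b.term[2:-1] if b.term.startswith("s(") else b.term
            x = df.loc[df[PC_COLUMN] == b.pc, name].to_numpy(dtype=float)
            eps = 1e-5 * max(sds[name], 1e-12)
            lo = pd.DataFrame({name: x - eps, PC_COLUMN: b.pc})
            hi = pd.DataFrame({name: x + eps, PC_COLUMN: b.pc})
            for t in covs:
                if t != name:
                    lo[t] = design.centers[t]
                    hi[t] = design.centers[t]
            Xl, Xh = design.build(lo), design.build(hi)
            G = (Xh - Xl) / (2 * eps)  # gradient rows
            gbar = G.mean(axis=0) * sds[name]
            est = float(gbar @ fit.beta)
            se = float(np.sqrt(max(gbar @ fit.cov_beta @ gbar, 0.0)))
            rows.append(
                EffectSize(
                    name, b.pc, est, est - z * se, est + z * se,
                    bool(est - z * se > 0 or est + z * se < 0),
                )
            )
    else:
        raise GammError(f"unknown effect-size method: {method!r}")

    return pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "pc": r.pc,
                "estimate": r.estimate,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def select_variance_structure(
    table: LongShapeTable,
    formula: FormulaSpec | None = None,
    candidates: tuple[str | None, ...] = (None, "temperature", "chla"),
    method: str = "REML",
) -> tuple[GammFit, pd.DataFrame]:
    """AICc selection among identity and exponential variance structures.

    Returns the winning REML fit and the comparison table (the identity
    fit is the LRT reference for each exponential candidate).
    """
    fits: dict[str, GammFit] = {}
    nesting = []
    for cov in candidates:
        if cov is None:
            fits["identity"] = fit_gamm(
                table, formula, VarianceStructure("identity"), method
            )
        else:
            name = f"exp({cov})"
            fits[name] = fit_gamm(
                table, formula, VarianceStructure("exponential", cov), method
            )
            nesting.append(("identity", name))
    comp = compare_models(fits, nesting if "identity" in fits else None)
    best = comp["AICc"].idxmin()
    return fits[best], comp
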