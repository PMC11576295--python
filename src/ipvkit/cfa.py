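"""Confirmatory factor analysis by maximum likelihood on a covariance matrix.

Implements simple-structure CFA (every item loads on exactly one factor)
with factor variances fixed to 1 for identification, so the solution is
reported directly in completely standardized form.  The discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

is minimized by L-BFGS with analytic gradients.  Factor correlations are
parameterized through hyperspherical Cholesky angles (guaranteeing a
positive semi-definite correlation matrix with unit diagonal) and
uniquenesses through their logarithm (guaranteeing positivity; a
uniqueness pinned at its lower bound is flagged as a Heywood case).

Because the model is scale invariant, estimation internally rescales S to
a correlation matrix; chi-square and all fit measures are unaffected and
standardized loadings fall out directly.

A Satorra-Bentler-style scaled test statistic is available when raw data
are supplied: the asymptotic covariance of the sample (co)variances is
estimated from fourth-order sample moments and the usual scaling factor
c = tr(U Gamma) / df rescales the normal-theory chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "FactorModelSpec",
    "CovarianceSummary",
    "FittedCFA",
    "FitIndices",
    "sample_covariance",
    "fit_ml",
    "independence_baseline",
    "satorra_bentler",
    "fit_indices",
    "rmsea_ci",
    "compare_models",
    "single_factor_spec",
    "correlated_spec",
]

_THETA_FLOOR = 1e-6
_ANGLE_EPS = 1e-3


# ---------------------------------------------------------------------------
# model specification and containers


@dataclass(frozen=True)
class FactorModelSpec:
    """Simple-structure loading pattern plus factor-covariance structure."""

    item_ids: tuple[str, ...]
    factor_ids: tuple[str, ...]
    loading_of: dict[str, str]  # item -> factor
    structure: str = "correlated_free"  # or "single_factor"

    def __post_init__(self):
        if self.structure not in ("single_factor", "correlated_free"):
            raise ValueError(f"unknown structure {self.structure!r}")
        missing = [i for i in self.item_ids if i not in self.loading_of]
        if missing:
            raise ValueError(f"items without a factor: {missing}")
        used = {self.loading_of[i] for i in self.item_ids}
        empty = set(self.factor_ids) - used
        if empty:
            raise ValueError(f"factors without items: {sorted(empty)}")
        if self.structure == "single_factor" and len(self.factor_ids) != 1:
            raise ValueError("single_factor structure requires exactly one factor")

    @property
    def n_factors(self) -> int:
        return len(self.factor_ids)

    def factor_index(self) -> np.ndarray:
        """Column index of each item's factor, in item order."""
        pos = {f: k for k, f in enumerate(self.factor_ids)}
        return np.array([pos[self.loading_of[i]] for i in self.item_ids])

    def n_free_params(self) -> int:
        p, m = len(self.item_ids), self.n_factors
        n_phi = m * (m - 1) // 2 if self.structure == "correlated_free" else 0
        return 2 * p + n_phi

    def degrees_of_freedom(self) -> int:
        p = len(self.item_ids)
        return p * (p + 1) // 2 - self.n_free_params()


def single_factor_spec(item_ids, factor_id: str = "g") -> FactorModelSpec:
    items = tuple(item_ids)
    return FactorModelSpec(
        item_ids=items,
        factor_ids=(factor_id,),
        loading_of={i: factor_id for i in items},
        structure="single_factor",
    )


def correlated_spec(items_by_factor: dict[str, list[str]]) -> FactorModelSpec:
    loading_of = {i: f for f, ids in items_by_factor.items() for i in ids}
    item_ids = tuple(i for ids in items_by_factor.values() for i in ids)
    return FactorModelSpec(
        item_ids=item_ids,
        factor_ids=tuple(items_by_factor),
        loading_of=loading_of,
        structure="correlated_free",
    )


@dataclass
class CovarianceSummary:
    S: pd.DataFrame  # item x item sample covariance (n-1 denominator)
    n: int
    means: pd.Series
    sds: pd.Series


def sample_covariance(data: pd.DataFrame) -> CovarianceSummary:
    """Unbiased sample covariance of a respondent x item matrix."""
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 respondents")
    sds = data.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise ValueError(f"constant columns {bad}")
    S = data.cov()
    S = (S + S.T) / 2
    return CovarianceSummary(S=S, n=n, means=data.mean(), sds=sds)


@dataclass
class FittedCFA:
    spec: FactorModelSpec
    lambda_std: pd.Series  # completely standardized loadings, item order
    phi: pd.DataFrame  # factor correlation matrix
    theta: pd.Series  # standardized uniquenesses
    f_min: float
    chi2: float
    df: int
    n: int
    converged: bool
    n_iter: int
    heywood_items: tuple[str, ...] = ()
    sb_c: float | None = None  # Satorra-Bentler scaling factor
    chi2_scaled: float | None = None
    sb_flag: str | None = None
    sample_corr: pd.DataFrame | None = field(default=None, repr=False)
    implied_corr: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def items(self) -> tuple[str, ...]:
        return self.spec.item_ids


# ---------------------------------------------------------------------------
# hyperspherical parameterization of a correlation matrix


def _chol_from_angles(angles: np.ndarray, m: int) -> np.ndarray:
    """Lower-triangular L with unit-norm rows from m(m-1)/2 angles."""
    L = np.zeros((m, m))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, m):
        a = angles[pos : pos + i]
        pos += i
        sin_prod = 1.0
        for j in range(i):
            L[i, j] = math.cos(a[j]) * sin_prod
            sin_prod *= math.sin(a[j])
        L[i, i] = sin_prod
    return L

def _angles_from_corr(phi: np.ndarray) -> np.ndarray:
    """Invert the spherical map for a positive-definite correlation matrix."""
    m = phi.shape[0]
    L = np.linalg.cholesky(phi)
    angles = []
    for i in range(1, m):
        sin_prod = 1.0
        for j in range(i):
            c = L[i, j] / sin_prod if sin_prod > 1e-12 else 0.0
            a = math.acos(min(1.0, max(-1.0, c)))
            a = min(max(a, _ANGLE_EPS), math.pi - _ANGLE_EPS)
            angles.append(a)
            sin_prod *= math.sin(a)
    return np.array(angles)

def _grad_angles(G_L: np.ndarray, angles: np.ndarray, m: int) -> np.ndarray:
    """Chain dF/dL (= G_L) through the spherical map to dF/dangles."""
    grad = np.zeros_like(angles)
    pos = 0
    for i in range(1, m):
        a = angles[pos : pos + i]
        sin_a, cos_a = np.sin(a), np.cos(a)
        for t in range(i):
            total = 0.0
            # entries L[i, j] for j in [t, i-1] and L[i, i] depend on a[t]
            for j in range(t, i):
                prod = np.prod(sin_a[:j][np.arange(j) != t]) if j > 0 else 1.0
                if t < j:
                    d = cos_a[j] * cos_a[t] * prod
                else:  # t == j
                    d = -sin_a[j] * prod
                total += G_L[i, j] * d
            prod = np.prod(sin_a[np.arange(i) != t])
            total += G_L[i, i] * cos_a[t] * prod
            grad[pos + t] = total
        pos += i
    return grad


# ---------------------------------------------------------------------------
# ML estimation


def _to_correlation(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return R, d

def _initial_values(R: np.ndarray, spec: FactorModelSpec):
    """Deterministic start: per-block principal components and composite
    correlations (shrunk toward independence until positive definite)."""
    fidx = spec.factor_index()
    p, m = R.shape[0], spec.n_factors
    lam0 = np.empty(p)
    for k in range(m):
        mask = fidx == k
        block = R[np.ix_(mask, mask)]
        w, v = np.linalg.eigh(block)
        pc = v[:, -1] * math.sqrt(max(w[-1], 1e-3))
        if pc.sum() < 0:
            pc = -pc
        lam0[mask] = np.clip(pc * 0.9, 0.05, 0.95)
    phi0 = np.eye(m)
    if m > 1:
        for f in range(m):
            for g in range(f + 1, m):
                bf, bg = fidx == f, fidx == g
                wf = np.mean(R[np.ix_(bf, bf)][~np.eye(bf.sum(), dtype=bool)]) if bf.sum() > 1 else 1.0
                wg = np.mean(R[np.ix_(bg, bg)][~np.eye(bg.sum(), dtype=bool)]) if bg.sum() > 1 else 1.0
                cross = np.mean(R[np.ix_(bf, bg)])
                denom = math.sqrt(max(wf, 0.05) * max(wg, 0.05))
                phi0[f, g] = phi0[g, f] = np.clip(cross / denom, -0.95, 0.95)
        # shrink toward identity until comfortably positive definite
        for _ in range(40):
            if np.linalg.eigvalsh(phi0).min() > 1e-3:
                break
            phi0 = 0.9 * phi0 + 0.1 * np.eye(m)
    theta0 = np.clip(1.0 - lam0**2, 0.05, 1.0)
    return lam0, phi0, theta0


def fit_ml(
    cov: CovarianceSummary,
    spec: FactorModelSpec,
    *,
    gtol: float = 1e-8,
    max_iter: int = 10000,
) -> FittedCFA:
    """Fit the CFA by maximum likelihood; returns the standardized solution.

    The optimizer is deterministic (principal-axis style initialization, no
    randomness).  Non-convergence is reported through ``converged`` rather
    than raised; Heywood cases (uniquenesses clamped at 1e-6) are listed in
    ``heywood_items``.
    """
    items = list(spec.item_ids)
    missing = set(items) - set(cov.S.columns)
    if missing:
        raise ValueError(f"items not present in covariance: {sorted(missing)}")
    S_full = cov.S.loc[items, items].to_numpy(dtype=float)
    eigmin = np.linalg.eigvalsh(S_full).min()
    if eigmin <= 0:
        raise ValueError(f"sample covariance not positive definite (min eig {eigmin:.3g})")

    R, _ = _to_correlation(S_full)
    p, m = len(items), spec.n_factors
    fidx = spec.factor_index()
    correlated = spec.structure == "correlated_free" and m > 1
    n_ang = m * (m - 1) // 2 if correlated else 0

    sgn, logdet_R = np.linalg.slogdet(R)
    lam0, phi0, theta0 = _initial_values(R, spec)
    ang0 = _angles_from_corr(phi0) if correlated else np.empty(0)
    x0 = np.concatenate([lam0, ang0, np.log(theta0)])

    cols = np.arange(p)

    def unpack(x):
        lam = x[:p]
        ang = x[p : p + n_ang]
        theta = np.exp(x[p + n_ang :])
        L = _chol_from_angles(ang, m) if correlated else np.eye(m)
        phi = L @ L.T
        Lam = np.zeros((p, m))
        Lam[cols, fidx] = lam
        return lam, ang, theta, L, phi, Lam

    def objective(x):
        lam, ang, theta, L, phi, Lam = unpack(x)
        Sigma = Lam @ phi @ Lam.T
        Sigma[np.diag_indices(p)] += theta
        try:
            c, low = cho_factor(Sigma, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Sinv_R = cho_solve((c, low), R, check_finite=False)
        f = logdet + np.trace(Sinv_R) - logdet_R - p
        # Omega = Sigma^-1 (Sigma - R) Sigma^-1 = Sigma^-1 - Sigma^-1 R Sigma^-1
        Sigma_inv = cho_solve((c, low), np.eye(p), check_finite=False)
        Omega = Sigma_inv - Sinv_R @ Sigma_inv
        Omega = (Omega + Omega.T) / 2
        g_lam = 2.0 * (Omega @ Lam @ phi)[cols, fidx]
        g_theta = np.diag(Omega) * theta  # wrt log-uniqueness
        if correlated:
            M = Lam.T @ Omega @ Lam
            G_L = 2.0 * M @ L
            g_ang = _grad_angles(G_L, ang, m)
        else:
            g_ang = np.empty(0)
        return f, np.concatenate([g_lam, g_ang, g_theta])

    bounds = (
        [(-2.0, 2.0)] * p
        + [(_ANGLE_EPS, math.pi - _ANGLE_EPS)] * n_ang
        + [(math.log(_THETA_FLOOR), math.log(10.0))] * p
    )
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 5 * max_iter, "ftol": 1e-14, "gtol": gtol},
    )
    lam, ang, theta, L, phi, Lam = unpack(res.x)
    f_min = float(objective(res.x)[0])
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm < 1e-6 or f_min < 1e-10

    # sign alignment: each factor's loading sum positive
    for k in range(m):
        mask = fidx == k
        if lam[mask].sum() < 0:
            lam[mask] = -lam[mask]
            phi[k, :] *= -1
            phi[:, k] *= -1
            phi[k, k] = 1.0

    heywood = tuple(np.array(items)[theta <= _THETA_FLOOR * 1.01])
    # completely standardized solution
    diag_implied = lam**2 + theta
    lam_std = lam / np.sqrt(diag_implied)
    theta_std = theta / diag_implied
    Lam_std = np.zeros((p, m))
    Lam_std[cols, fidx] = lam_std
    implied_std = Lam_std @ phi @ Lam_std.T
    implied_std[np.diag_indices(p)] = 1.0

    n = cov.n
    chi2 = max(0.0, (n - 1) * f_min)
    return FittedCFA(
        spec=spec,
        lambda_std=pd.Series(lam_std, index=items, name="lambda_std"),
        phi=pd.DataFrame(phi, index=spec.factor_ids, columns=spec.factor_ids),
        theta=pd.Series(theta_std, index=items, name="theta"),
        f_min=f_min,
        chi2=chi2,
        df=spec.degrees_of_freedom(),
        n=n,
        converged=converged,
        n_iter=int(res.nit),
        heywood_items=heywood,
        sample_corr=pd.DataFrame(R, index=items, columns=items),
        implied_corr=pd.DataFrame(implied_std, index=items, columns=items),
    )


def independence_baseline(cov: CovarianceSummary, item_ids=None) -> FittedCFA:
    """Null model with a diagonal implied covariance (closed-form fit)."""
    items = list(item_ids) if item_ids is not None else list(cov.S.columns)
    S = cov.S.loc[items, items].to_numpy(dtype=float)
    R, _ = _to_correlation(S)
    p = len(items)
    sgn, logdet_R = np.linalg.slogdet(R)
    f_min = float(-logdet_R)
    spec = FactorModelSpec(
        item_ids=tuple(items),
        factor_ids=("null",),
        loading_of={i: "null" for i in items},
        structure="single_factor",
    )
    fit = FittedCFA(
        spec=spec,
        lambda_std=pd.Series(np.zeros(p), index=items),
        phi=pd.DataFrame([[1.0]], index=["null"], columns=["null"]),
        theta=pd.Series(np.ones(p), index=items),
        f_min=f_min,
        chi2=max(0.0, (cov.n - 1) * f_min),
        df=p * (p - 1) // 2,
        n=cov.n,
        converged=True,
        n_iter=0,
        sample_corr=pd.DataFrame(R, index=items, columns=items),
        implied_corr=pd.DataFrame(np.eye(p), index=items, columns=items),
    )
    return fit


# ---------------------------------------------------------------------------
# Satorra-Bentler scaling


def _vech_indices(p: int):
    rows, cols = np.tril_indices(p)
    return rows, cols

def _duplication_matrix(p: int) -> np.ndarray:
    rows, cols = _vech_indices(p)
    q = len(rows)
    D = np.zeros((p * p, q))
    for k, (i, j) in enumerate(zip(rows, cols)):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D

def _model_jacobian(fit: FittedCFA, baseline: bool = False) -> np.ndarray:
    """d vech(Sigma)/d theta at the fitted (standardized-scale) solution."""
    items = list(fit.items)
    p = len(items)
    rows, cols = _vech_indices(p)
    if baseline:
        cols_out = []
        for i in range(p):
            dS = np.zeros((p, p))
            dS[i, i] = 1.0
            cols_out.append(dS[rows, cols])
        return np.column_stack(cols_out)
    spec = fit.spec
    m = spec.n_factors
    fidx = spec.factor_index()
    lam = fit.lambda_std.to_numpy()
    phi = fit.phi.to_numpy()
    Lam = np.zeros((p, m))
    Lam[np.arange(p), fidx] = lam
    cols_out = []
    for i in range(p):  # loadings
        f = fidx[i]
        w = Lam @ phi[:, f]
        dS = np.zeros((p, p))
        dS[i, :] += w
        dS[:, i] += w
        cols_out.append(dS[rows, cols])
    if spec.structure == "correlated_free" and m > 1:  # factor correlations
        for f in range(m):
            for g in range(f + 1, m):
                dS = np.outer(Lam[:, f], Lam[:, g])
                dS = dS + dS.T
                cols_out.append(dS[rows, cols])
    for i in range(p):  # uniquenesses
        dS = np.zeros((p, p))
        dS[i, i] = 1.0
        cols_out.append(dS[rows, cols])
    return np.column_stack(cols_out)


def satorra_bentler(
    data: pd.DataFrame,
    fitted: FittedCFA,
    *,
    baseline: bool = False,
) -> FittedCFA:
    """Attach the scaled (mean-corrected) test statistic to a fitted model.

    The asymptotic covariance Gamma of the sample moments is estimated from
    fourth-order moments of the (per-column standardized) raw data, treating
    the standardizing constants as fixed.  The scaling factor is
    c = tr(U Gamma)/df with U the normal-theory residual weight projector;
    the scaled statistic is chi2 / c.  For df = 0 the factor is undefined
    and reported as 1 with a flag.
    """
    items = list(fitted.items)
    X = data[items].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("Satorra-Bentler scaling needs n > p")
    if fitted.df <= 0:
        fitted.sb_c = 1.0
        fitted.chi2_scaled = fitted.chi2
        fitted.sb_flag = "df=0: scaling undefined, factor set to 1"
        return fitted

    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    rows, cols = _vech_indices(p)
    B = Z[:, rows] * Z[:, cols]  # n x p(p+1)/2 per-observation moments
    B -= B.mean(axis=0)
    Gamma = (B.T @ B) / n

    Sigma = fitted.implied_corr.to_numpy()
    Sigma_inv = np.linalg.inv(Sigma)
    D = _duplication_matrix(p)
    K = np.kron(Sigma_inv, Sigma_inv)
    W = 0.5 * D.T @ K @ D
    Delta = _model_jacobian(fitted, baseline=baseline)
    WD = W @ Delta
    middle = Delta.T @ WD
    U = W - WD @ np.linalg.solve(middle, WD.T)
    c = float(np.trace(U @ Gamma)) / fitted.df
    if c <= 0:
        fitted.sb_c = 1.0
        fitted.chi2_scaled = fitted.chi2
        fitted.sb_flag = f"non-positive scaling estimate ({c:.3g}); factor set to 1"
        return fitted
    fitted.sb_c = c
    fitted.chi2_scaled = fitted.chi2 / c
    fitted.sb_flag = None
    return fitted


# ---------------------------------------------------------------------------
# fit indices


@dataclass
class FitIndices:
    chi2: float
    df: int
    chi2_df: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    cfi: float
    rmsea_robust: float | None = None
    cfi_robust: float | None = None
    flags: tuple[str, ...] = ()


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Confidence interval for RMSEA by inverting the noncentral chi-square
    CDF in its noncentrality parameter (Steiger-Lind approach)."""
    if df < 1 or n < 2 or chi2 <= 0:
        return (0.0, 0.0)
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def ncp_for(target):
        # find ncp with P(X <= chi2 | df, ncp) = target
        f = lambda ncp: stats.ncx2.cdf(chi2, df, ncp) - target
        if f(0.0) < 0:
            return 0.0
        hi = max(10.0, 2 * chi2)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2
        return optimize.brentq(f, 0.0, hi, xtol=1e-10)

    ncp_lo = ncp_for(lo_q)
    ncp_hi = ncp_for(hi_q)
    scale = df * (n - 1)
    return (math.sqrt(ncp_lo / scale), math.sqrt(ncp_hi / scale))


def _srmr(fit: FittedCFA) -> float:
    R = fit.sample_corr.to_numpy()
    Sig = fit.implied_corr.to_numpy()
    rows, cols = _vech_indices(R.shape[0])
    resid = (R - Sig)[rows, cols]
    return float(np.sqrt(np.mean(resid**2)))


def fit_indices(fitted: FittedCFA, baseline: FittedCFA | None = None, n: int | None = None) -> FitIndices:
    """Standard fit-index suite: chi2/df, RMSEA (+90% CI), SRMR, CFI.

    Robust (population-corrected, mean-scaled) RMSEA and CFI are filled in
    when Satorra-Bentler scaling factors are available on the fitted (and,
    for CFI, the baseline) models.
    """
    n = n or fitted.n
    if baseline is not None and set(baseline.items) != set(fitted.items):
        raise ValueError("baseline must be fit on the same items")
    flags = []
    chi2, df = fitted.chi2, fitted.df
    if df > 0:
        chi2_df = chi2 / df
        rmsea = math.sqrt(max(0.0, (chi2 - df) / (df * (n - 1))))
        ci = rmsea_ci(chi2, df, n)
    else:
        chi2_df, rmsea, ci = 0.0, 0.0, (0.0, 0.0)
        flags.append("df=0: rmsea undefined, reported 0")
    srmr = _srmr(fitted)
    if baseline is not None:
        num = max(0.0, chi2 - df)
        den = max(chi2 - df, baseline.chi2 - baseline.df, 0.0)
        cfi = 1.0 - num / den if den > 0 else 1.0
    else:
        cfi = float("nan")
        flags.append("no baseline: cfi not computed")

    rmsea_rob = cfi_rob = None
    if fitted.sb_c is not None and df > 0:
        c = fitted.sb_c
        rmsea_rob = math.sqrt(max(0.0, (chi2 - c * df) / (df * (n - 1))))
        if baseline is not None and baseline.sb_c is not None:
            cb = baseline.sb_c
            num = max(0.0, chi2 - c * df)
            den = max(chi2 - c * df, baseline.chi2 - cb * baseline.df, 0.0)
            cfi_rob = 1.0 - num / den if den > 0 else 1.0
    return FitIndices(
        chi2=chi2,
        df=df,
        chi2_df=chi2_df,
        rmsea=rmsea,
        rmsea_ci90=ci,
        srmr=srmr,
        cfi=cfi,
        rmsea_robust=rmsea_rob,
        cfi_robust=cfi_rob,
        flags=tuple(flags),
    )


def compare_models(fit_a: FittedCFA, fit_b: FittedCFA, idx_a: FitIndices | None = None, idx_b: FitIndices | None = None) -> dict:
    """Side-by-side comparison with (unscaled) chi-square difference."""
    if set(fit_a.items) != set(fit_b.items):
        raise ValueError("models must be fit on the same items")
    nested = fit_a.df != fit_b.df
    rec = {
        "chi2_a": fit_a.chi2,
        "chi2_b": fit_b.chi2,
        "df_a": fit_a.df,
        "df_b": fit_b.df,
        "delta_chi2": fit_a.chi2 - fit_b.chi2,
        "delta_df": fit_a.df - fit_b.df,
        "nested_candidate": nested,
    }
    if idx_a is not None and idx_b is not None:
        for name in ("rmsea", "srmr", "cfi", "chi2_df"):
            rec[f"delta_{name}"] = getattr(idx_a, name) - getattr(idx_b, name)
    return rec
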