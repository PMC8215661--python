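"""Variable selection, community turnover, and constrained ordination.

Community turnover is analysed on Hellinger-transformed frequencies, where
Euclidean distance is ecologically meaningful: unconstrained structure via
PCoA, constrained structure via partial redundancy analysis (RDA) with the
site as conditioning block, forward-backward variable selection driven by
permutation tests, and variance partitioning via differences of Ezekiel
adjusted R^2.  Environmental collinearity is screened beforehand by
iteratively removing variables with VIF = 1/(1-R^2) above a threshold
(default 5).  A robust (Tukey-bisquare IRLS) log-log regression supports
marker-vs-marker frequency comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa


# ---------------------------------------------------------------------------
# VIF selection
# ---------------------------------------------------------------------------

def vif_values(env: pd.DataFrame, variables) -> pd.Series:
    """VIF = 1/(1-R^2) of each variable regressed on the others (with
    intercept); perfect collinearity yields inf."""
    X = env[list(variables)].astype(float)
    out = {}
    for v in variables:
        others = [w for w in variables if w != v]
        if not others:
            out[v] = 1.0
            continue
        design = sm.add_constant(X[others].to_numpy())
        r2 = sm.OLS(X[v].to_numpy(), design).fit().rsquared
        out[v] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_select(
    env: pd.DataFrame, variables, threshold: float = 5.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the variable with the largest VIF until all VIFs are
    at or below ``threshold``.

    Ties break deterministically: larger VIF first, then alphabetical order.
    Returns (kept variables, removal trace with the VIF at removal).
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    if len(env) <= len(variables):
        raise ValueError("need more samples than variables")
    trace = []
    remaining = sorted(variables)
    while True:
        vifs = vif_values(env, remaining)
        worst = vifs.sort_index().sort_values(kind="stable", ascending=False).index[0]
        if vifs[worst] <= threshold:
            break
        trace.append({"removed": worst, "vif": float(vifs[worst])})
        remaining = [v for v in remaining if v != worst]
        if len(remaining) == 1:
            break
    kept = [v for v in variables if v in remaining]
    return kept, pd.DataFrame(trace, columns=["removed", "vif"])


# ---------------------------------------------------------------------------
# Hellinger transform and PCoA
# ---------------------------------------------------------------------------

def hellinger(matrix):
    """Square roots of within-row relative frequencies.

    All-zero rows are left as zeros (with a warning); negative entries are
    rejected.  Accepts and returns either a DataFrame or an ndarray.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    M = np.asarray(matrix, dtype=float)
    if (M < 0).any():
        raise ValueError("community matrix must be non-negative")
    sums = M.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        warnings.warn("all-zero rows left untransformed")
    H = np.sqrt(M / np.where(sums > 0, sums, 1.0))
    if is_frame:
        return pd.DataFrame(H, index=matrix.index, columns=matrix.columns)
    return H


def pcoa(dist) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (double-centering + eigendecomposition) of a
    symmetric distance matrix.

    Returns (coordinates over positive-eigenvalue axes, all eigenvalues in
    non-increasing order, negatives included for diagnostics).
    """
    if isinstance(dist, pd.DataFrame):
        ids = [str(i) for i in dist.index]
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        ids = [str(i) for i in range(len(D))]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix(D, ids))
    eigvals = res.eigvals.to_numpy()
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    coords = res.samples.to_numpy()[:, order]
    keep = eigvals > max(eigvals.max(), 0.0) * 1e-12
    coords = pd.DataFrame(
        coords[:, keep],
        index=ids,
        columns=[f"PCo{i + 1}" for i in range(int(keep.sum()))],
    )
    return coords, eigvals


# ---------------------------------------------------------------------------
# partial RDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    axes: pd.DataFrame
    eigenvalues: np.ndarray
    constrained_R2: float
    adjusted_R2: float
    p_value: float | None = None
    selected_variables: list[str] = field(default_factory=list)
    per_variable: pd.DataFrame | None = None


def _condition_design(env: pd.DataFrame, condition) -> np.ndarray:
    """Intercept + conditioning block (categoricals as treatment contrasts)."""
    n = len(env)
    blocks = [np.ones((n, 1))]
    for c in condition or ():
        col = env[c]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            blocks.append(dummies)
    return np.hstack(blocks)


def _residualize(M: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ beta


def _standardize(env: pd.DataFrame, variables) -> np.ndarray:
    X = env[list(variables)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant predictor(s): {bad}")
    return (X - X.mean(axis=0)) / sd


def rda(
    community,
    env: pd.DataFrame,
    variables,
    condition=("Site",),
    n_perm: int = 999,
    seed=None,
) -> OrdinationResult:
    """Partial redundancy analysis of a (Hellinger-transformed) community.

    Community and standardised predictors are residualised on the conditioning
    block, the community is regressed on the predictors, and the fitted values
    are eigendecomposed.  Constrained R^2 is the fitted fraction of the
    conditioned community variance; adjusted R^2 follows Ezekiel,
    1 - (1-R^2)(n-1)/(n-m-1).  The permutation p-value permutes rows of the
    residualised community (reduced-model permutation), with the
    include-observed convention.
    """
    variables = list(variables)
    Y = np.asarray(community, dtype=float)
    index = community.index if isinstance(community, pd.DataFrame) else pd.RangeIndex(len(Y))
    n = Y.shape[0]
    if n <= len(variables) + 1:
        raise ValueError("need more samples than predictors")
    X = _standardize(env, variables)
    C = _condition_design(env, condition)
    Yr = _residualize(Y - Y.mean(axis=0), C)
    Xr = _residualize(X, C)

    # detect aliasing of predictors by the conditioning block
    _, Rq, piv = linalg.qr(Xr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    tol = max(Xr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if (diag <= tol).any():
        aliased = [variables[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(f"predictor(s) aliased with the condition: {aliased}")

    B, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
    F = Xr @ B
    ss_total = float((Yr**2).sum())
    ss_fit = float((F**2).sum())
    r2 = ss_fit / ss_total if ss_total > 0 else 0.0
    m = len(variables)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)

    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    eigenvalues = (s**2) / (n - 1)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    axes = pd.DataFrame(
        U[:, :rank] * s[:rank],
        index=index,
        columns=[f"RDA{i + 1}" for i in range(rank)],
    )

    p_value = None
    if n_perm and n_perm > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # orthonormal basis of the conditioned predictor space
        Ux, sx, _ = np.linalg.svd(Xr, full_matrices=False)
        Q = Ux[:, sx > sx[0] * 1e-10] if sx.size and sx[0] > 0 else Ux[:, :0]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = Yr[perm]
            r2p = float(((Q.T @ Yp) ** 2).sum()) / ss_total
            if r2p >= r2 - 1e-12:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)

    return OrdinationResult(
        axes=axes,
        eigenvalues=eigenvalues[: max(rank, 1)],
        constrained_R2=r2,
        adjusted_R2=adj,
        p_value=p_value,
        selected_variables=variables,
    )


def stepwise_select(
    community,
    env: pd.DataFrame,
    variables,
    condition=("Site",),
    n_perm: int = 999,
    alpha_enter: float = 0.05,
    seed=None,
    max_steps: int = 100,
) -> tuple[list[str], pd.DataFrame]:
    """Forward-backward selection on marginal permutation p-values.

    Forward: among the remaining candidates, test each conditioned on the
    current model (plus the conditioning block) and add the one with the
    lowest p if p < alpha_enter (ties: higher R^2, then name).  Backward:
    re-test each selected variable conditioned on the others and drop any
    whose p rises above alpha_enter (worst first).  Deterministic under a
    fixed seed.  Returns (selected variables, decision trace).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    variables = list(variables)
    selected: list[str] = []
    trace = []
    for _ in range(max_steps):
        changed = False
        # forward
        remaining = [v for v in variables if v not in selected]
        best = None
        for v in sorted(remaining):
            res = rda(
                community, env, [v],
                condition=tuple(condition) + tuple(selected),
                n_perm=n_perm, seed=rng,
            )
            key = (res.p_value, -res.constrained_R2, v)
            if best is None or key < best[0]:
                best = (key, v, res)
        if best is not None and best[2].p_value < alpha_enter:
            selected.append(best[1])
            trace.append({"action": "add", "variable": best[1], "p": best[2].p_value})
            changed = True
        # backward
        while len(selected) > 1:
            worst = None
            for v in sorted(selected):
                others = [w for w in selected if w != v]
                res = rda(
                    community, env, [v],
                    condition=tuple(condition) + tuple(others),
                    n_perm=n_perm, seed=rng,
                )
                key = (-res.p_value, v)
                if worst is None or key < worst[0]:
                    worst = (key, v, res)
            if worst is not None and worst[2].p_value > alpha_enter:
                selected.remove(worst[1])
                trace.append({"action": "drop", "variable": worst[1], "p": worst[2].p_value})
                changed = True
            else:
                break
        if not changed:
            break
    return selected, pd.DataFrame(trace, columns=["action", "variable", "p"])


def variance_partition(
    community, env: pd.DataFrame, selected, condition=("Site",)
) -> pd.Series:
    """Partial adjusted R^2 of each selected variable: adjusted R^2 of the
    full model minus that of the model without the variable (conditioning
    fixed)."""
    selected = list(selected)
    if not selected:
        raise ValueError("selected variable set is empty")
    full = rda(community, env, selected, condition=condition, n_perm=0).adjusted_R2
    out = {}
    for v in selected:
        others = [w for w in selected if w != v]
        if others:
            reduced = rda(community, env, others, condition=condition, n_perm=0).adjusted_R2
        else:
            reduced = 0.0
        out[v] = full - reduced
    return pd.Series(out, name="partial_adjusted_R2").sort_values(ascending=False)


# ---------------------------------------------------------------------------
# robust marker-vs-marker regression
# ---------------------------------------------------------------------------

@dataclass
class RobustFit:
    slope: float
    intercept: float
    weights: np.ndarray
    r_squared: float
    n_excluded: int = 0


def irls_fit(x, y, tuning: float = 4.685) -> RobustFit:
    """Tukey-bisquare IRLS line fit (robust to gross outliers).

    Weights w = (1 - (r/(c*s))^2)^2 for |r| < c*s, else 0, with s a MAD-based
    scale; iterates weighted least squares to convergence.  The reported R^2
    is the weighted coefficient of determination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least three finite observations")
    x, y = x[ok], y[ok]
    design = sm.add_constant(x)
    norm = sm.robust.norms.TukeyBiweight(c=tuning)
    model = sm.RLM(y, design, M=norm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=50, tol=1e-8)
    resid = y - res.fittedvalues
    # final-iteration bisquare weights; a perfect fit (scale 0) keeps them at 1
    w = norm.weights(resid / res.scale) if res.scale > 0 else np.ones_like(resid)
    w = np.asarray(w, dtype=float)
    ybar = np.average(y, weights=w) if w.sum() > 0 else y.mean()
    ss_res = float((w * resid**2).sum())
    ss_tot = float((w * (y - ybar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RobustFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        weights=w,
        r_squared=r2,
        n_excluded=int((~ok).sum()),
    )


def marker_regression(freq_x, freq_y, tuning: float = 4.685) -> RobustFit:
    """Robust log10-log10 regression between two markers' frequencies of the
    same clade, excluding pairs where either frequency is zero (count kept in
    ``n_excluded``)."""
    fx = np.asarray(freq_x, dtype=float)
    fy = np.asarray(freq_y, dtype=float)
    ok = (fx > 0) & (fy > 0) & np.isfinite(fx) & np.isfinite(fy)
    fit = irls_fit(np.log10(fx[ok]), np.log10(fy[ok]), tuning=tuning)
    fit.n_excluded = int((~ok).sum())
    return fit
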