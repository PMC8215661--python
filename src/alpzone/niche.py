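"""OMI niche inference with a dual permutation criterion for specialization.

For each taxon, samples are weighted by the taxon's relative read abundance in
the standardised environmental space.  The taxon's niche inertia (weighted
mean squared distance of samples from the origin, i.e. from the average
environment) decomposes exactly into:

* marginality (OMI) - squared distance of the abundance-weighted niche centre
  from the origin;
* marginal tolerance - weighted variance of sample positions projected on the
  marginality axis (the direction from origin to niche centre);
* residual tolerance - the remaining, orthogonal variance.

A taxon is called specialized when its marginality is larger than expected
under random placement (upper-tail permutation test) OR its marginal
tolerance is smaller than expected (lower-tail), each at level alpha; both
null distributions come from permuting the taxon's weights across samples.

Per-variable optimal ranges (Fig-9-style density bands) use an
abundance-weighted Gaussian kernel density: the peak is the density argmax,
the range the smallest interval around the peak holding a target fraction of
the weighted mass, and a Mann-Whitney test compares the taxon's read-weighted
positions with the full set of sampled positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


def standardize_env(env: pd.DataFrame, variables) -> pd.DataFrame:
    """Centre and scale continuous variables to zero mean, unit variance
    (population scaling) over the samples."""
    X = env[list(variables)].astype(float)
    sd = X.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(f"constant variable(s): {list(sd.index[sd == 0])}")
    return (X - X.mean()) / sd


def _omi_parts(Z: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    """(inertia, marginality, marginal tolerance, residual tolerance) for one
    normalised weight vector."""
    center = w @ Z
    marg = float(center @ center)
    inertia = float(w @ (Z**2).sum(axis=1))
    if marg > 0.0:
        u = center / np.sqrt(marg)
        proj = Z @ u
        mtol = float(w @ (proj - np.sqrt(marg)) ** 2)
    else:
        # centre exactly at the origin: the marginality axis is undefined
        mtol = 0.0
    rtol = inertia - marg - mtol
    return inertia, marg, mtol, max(rtol, 0.0)


def omi(community: pd.DataFrame, env: pd.DataFrame, variables) -> pd.DataFrame:
    """OMI decomposition for every taxon of a sample x taxon frequency matrix.

    Taxa with zero total frequency are excluded; taxa present in a single
    sample have zero tolerances and are flagged degenerate.
    """
    Z = standardize_env(env.loc[community.index], variables).to_numpy()
    rows = {}
    for taxon in community.columns:
        w = community[taxon].to_numpy(dtype=float)
        total = w.sum()
        if total <= 0:
            continue
        w = w / total
        inertia, marg, mtol, rtol = _omi_parts(Z, w)
        rows[taxon] = {
            "inertia": inertia,
            "marginality": marg,
            "marginal_tolerance": mtol,
            "residual_tolerance": rtol,
            "n_occupied": int((w > 0).sum()),
            "degenerate": bool((w > 0).sum() == 1),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "taxon"
    return out


def specialization_test(
    community: pd.DataFrame,
    env: pd.DataFrame,
    variables,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """OMI decomposition plus the dual permutation criterion.

    p_marginality: share of permutations with marginality >= observed
    (upper tail); p_tolerance: share with marginal tolerance <= observed
    (lower tail); both with the include-observed convention, so the smallest
    attainable p is 1/(n_perm+1).  ``specialized`` is the union of the two
    alpha-level rejections.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = standardize_env(env.loc[community.index], variables).to_numpy()
    n = Z.shape[0]
    summary = omi(community, env, variables)
    p_marg, p_tol = {}, {}
    for taxon in summary.index:
        w = community[taxon].to_numpy(dtype=float)
        w = w / w.sum()
        obs_marg = summary.loc[taxon, "marginality"]
        obs_mtol = summary.loc[taxon, "marginal_tolerance"]
        P = rng.permuted(np.tile(w, (n_perm, 1)), axis=1)  # n_perm x n
        centers = P @ Z  # n_perm x k
        marg = (centers**2).sum(axis=1)
        norm = np.sqrt(np.where(marg > 0, marg, 1.0))
        U = centers / norm[:, None]
        proj = Z @ U.T  # n x n_perm
        mtol = (P * (proj.T - norm[:, None]) ** 2).sum(axis=1)
        mtol[marg <= 0] = 0.0
        p_marg[taxon] = (1 + int((marg >= obs_marg - 1e-12).sum())) / (n_perm + 1)
        p_tol[taxon] = (1 + int((mtol <= obs_mtol + 1e-12).sum())) / (n_perm + 1)
    summary["p_marginality"] = pd.Series(p_marg)
    summary["p_tolerance"] = pd.Series(p_tol)
    summary["specialized"] = (summary["p_marginality"] <= alpha) | (
        summary["p_tolerance"] <= alpha
    )
    return summary


@dataclass
class OptimalRange:
    """Abundance-weighted optimal range of one taxon along one variable."""

    taxon: str
    variable: str
    peak: float
    range_low: float
    range_high: float
    median: float
    mw_p: float | None
    degenerate: bool = False


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def optimal_range(
    community: pd.DataFrame,
    env: pd.DataFrame,
    variable: str,
    taxon: str,
    bandwidth="silverman",
    mass: float = 0.5,
    n_grid: int = 512,
    expansion: int = 200,
) -> OptimalRange:
    """Weighted-KDE optimal range of ``taxon`` along ``variable``.

    ``mass`` is the weighted density fraction the grey band must hold
    (default 50%).  The Mann-Whitney p compares the taxon's read-weighted
    positions (weights expanded to ``expansion`` pseudo-observations) against
    all sampled positions, two-sided.
    """
    x = env.loc[community.index, variable].to_numpy(dtype=float)
    w = community[taxon].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError(f"taxon {taxon} absent from the community matrix")
    w = w / w.sum()
    occupied = x[w > 0]
    if len(np.unique(occupied)) < 2:
        v = float(occupied[0])
        return OptimalRange(taxon, variable, v, v, v, v, None, degenerate=True)

    kde = stats.gaussian_kde(x, bw_method=bandwidth, weights=w)
    pad = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    dens = kde(grid)
    peak_i = int(np.argmax(dens))
    # smallest interval around the peak holding `mass` of the density
    total = dens.sum()
    lo = hi = peak_i
    acc = dens[peak_i]
    while acc < mass * total and (lo > 0 or hi < n_grid - 1):
        left = dens[lo - 1] if lo > 0 else -np.inf
        right = dens[hi + 1] if hi < n_grid - 1 else -np.inf
        if left >= right:
            lo -= 1
            acc += dens[lo]
        else:
            hi += 1
            acc += dens[hi]

    median = _weighted_median(x, w)
    pseudo = np.repeat(x, np.round(w * expansion).astype(int))
    if len(np.unique(pseudo)) < 2:
        mw_p = None
    else:
        mw_p = float(stats.mannwhitneyu(pseudo, x, alternative="two-sided").pvalue)
    return OptimalRange(
        taxon=taxon,
        variable=variable,
        peak=float(grid[peak_i]),
        range_low=float(grid[lo]),
        range_high=float(grid[hi]),
        median=median,
        mw_p=mw_p,
    )


def optimal_ranges(
    community: pd.DataFrame, env: pd.DataFrame, variables, taxa=None, **kwargs
) -> pd.DataFrame:
    """Optimal ranges for each (taxon, variable) pair as a flat table."""
    taxa = list(taxa) if taxa is not None else list(community.columns)
    rows = []
    for taxon in taxa:
        if community[taxon].sum() <= 0:
            continue
        for var in variables:
            r = optimal_range(community, env, var, taxon, **kwargs)
            rows.append(
                {
                    "taxon": r.taxon,
                    "variable": r.variable,
                    "peak": r.peak,
                    "range_low": r.range_low,
                    "range_high": r.range_high,
                    "center": (r.range_low + r.range_high) / 2.0,
                    "median": r.median,
                    "mw_p": r.mw_p,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class NichePCAResult:
    scores: pd.DataFrame
    percent_variance: np.ndarray
    loadings: pd.DataFrame
    mw_p: float | None
    classes: tuple[str, str] | None


def niche_pca(
    centers: pd.DataFrame, classes: pd.Series | None = None, class_pair=None
) -> NichePCAResult:
    """PCA of specialized taxa described by their optimum-interval centres.

    ``centers`` is taxa x variables (midpoints of the per-variable optimal
    ranges); columns are centred/scaled, constant columns dropped with a
    warning.  When two classes are designated (or the two most frequent
    levels of ``classes`` by default), axis-1 scores are compared between
    them with a two-sided Mann-Whitney test.
    """
    if len(centers) < 3:
        raise ValueError("need at least three specialized taxa")
    X = centers.astype(float)
    sd = X.std(ddof=0)
    const = list(sd.index[sd == 0])
    if const:
        warnings.warn(f"constant column(s) dropped: {const}")
        X = X.drop(columns=const)
        sd = sd.drop(const)
    Xs = (X - X.mean()) / sd
    n_comp = min(Xs.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Xs.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(scores, index=centers.index, columns=cols)
    loadings = pd.DataFrame(pca.components_.T, index=X.columns, columns=cols)
    pct = 100.0 * pca.explained_variance_ratio_

    mw_p = None
    pair = None
    if classes is not None:
        classes = classes.loc[centers.index]
        if class_pair is None:
            top = classes.value_counts().index[:2]
            class_pair = tuple(top) if len(top) == 2 else None
        if class_pair is not None:
            a = scores.loc[classes == class_pair[0], "PC1"]
            b = scores.loc[classes == class_pair[1], "PC1"]
            if len(a) and len(b):
                mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                pair = (str(class_pair[0]), str(class_pair[1]))
    return NichePCAResult(scores, pct, loadings, mw_p, pair)
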