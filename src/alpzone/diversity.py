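"""Hill-number diversity and its relation to environmental gradients.

The diversity of a community with relative frequencies p_i is summarised by
Hill numbers ^qD = (sum p_i^q)^(1/(1-q)), the effective number of equally
abundant species; q = 1 (the exponential of Shannon entropy) is the working
order here because it discounts both genuinely rare taxa and the low-frequency
artefactual variants that PCR generates.  Regional structure is partitioned as
beta = gamma / alpha with alpha the mean per-unit ^qD and gamma the ^qD of the
pooled community.

Gradient structure is assessed by discretising each continuous variable into
equal-width slices (seven by default), measuring the between-slice variance
fraction (one-way ANOVA R^2), testing with Kruskal-Wallis, and adjusting
p-values across variables by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import MOTUTable, validate_pcrs

logger = logging.getLogger(__name__)


def hill(freqs, q: float = 1.0) -> float:
    """Hill number ^qD of a (not necessarily normalised) frequency vector.

    q = 1 is computed as exp(-sum p ln p) with 0*ln(0) = 0; the general
    formula is continuous at q = 1 (values at q = 1 +/- 1e-6 agree).
    """
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("frequency vector sums to zero")
    if q < 0:
        raise ValueError("the order q must be non-negative")
    p = p[p > 0] / total
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def gamma_alpha_beta(matrix, q: float = 1.0) -> tuple[float, float, float]:
    """(gamma, mean alpha, beta = gamma/alpha) over a unit x taxon matrix.

    Rows are normalised to frequencies; gamma pools units with equal weight
    (mean of the row frequency vectors), matching alpha's equal weighting.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    rows = M / M.sum(axis=1, keepdims=True)
    alpha = float(np.mean([hill(r, q) for r in rows]))
    gamma = hill(rows.mean(axis=0), q)
    return gamma, alpha, gamma / alpha


def pcr_diversity(table: MOTUTable, pcrs: pd.DataFrame, q: float = 1.0) -> pd.Series:
    """^qD of every sample PCR (the paper-style per-PCR unit), indexed by
    pcr_id; empty PCRs are skipped."""
    pcrs = validate_pcrs(pcrs)
    cols = pcrs.loc[
        (pcrs["control_type"] == "sample") & pcrs["pcr_id"].isin(table.pcr_ids), "pcr_id"
    ]
    values = {}
    for c in cols:
        v = table.counts[c].to_numpy()
        if v.sum() > 0:
            values[c] = hill(v, q)
    return pd.Series(values, name=f"hill_q{q:g}")


def sample_diversity(community: pd.DataFrame, q: float = 1.0) -> pd.Series:
    """^qD per sample of an aggregated community matrix."""
    return pd.Series(
        {s: hill(community.loc[s].to_numpy(), q) for s in community.index},
        name=f"hill_q{q:g}",
    )


@dataclass
class SliceTest:
    """Diversity-vs-gradient slice test for one variable."""

    variable: str
    n_slices: int
    r_squared: float
    kw_p: float
    fdr_p: float = float("nan")
    slice_means: pd.DataFrame = field(default_factory=pd.DataFrame)


def slice_anova(
    values: pd.Series, env: pd.DataFrame, variable: str, n_slices: int = 7
) -> SliceTest:
    """Discretise ``variable`` into equal-width slices over its observed range
    and relate ``values`` (diversity per unit) to the slices.

    R^2 is the between-slice fraction of the total sum of squares (one-way
    ANOVA); significance comes from Kruskal-Wallis across slices.  Empty
    slices are merged away (logged); at least two occupied slices must remain.
    """
    common = values.index.intersection(env.index)
    if len(common) == 0:
        raise ValueError("values and env share no units")
    y = values.loc[common].astype(float)
    x = env.loc[common, variable].astype(float)
    bins = pd.cut(x, bins=n_slices, include_lowest=True)
    occupied = bins.value_counts()
    empty = occupied[occupied == 0]
    if len(empty) > 0:
        logger.info("%s: %d empty slice(s) merged with neighbours", variable, len(empty))
    groups = [y[bins == b].to_numpy() for b in occupied.index[occupied > 0]]
    if len(groups) < 2:
        raise ValueError(f"{variable}: fewer than two occupied slices")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    r2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    try:
        kw_p = float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        kw_p = 1.0
    means = pd.DataFrame(
        {
            "interval": [str(b) for b in occupied.index[occupied > 0]],
            "n": [len(g) for g in groups],
            "mean": [g.mean() for g in groups],
        }
    )
    se = np.array([g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan for g in groups])
    means["ci_low"] = means["mean"] - 1.96 * se
    means["ci_high"] = means["mean"] + 1.96 * se
    return SliceTest(variable, n_slices, r2, kw_p, slice_means=means)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def gradient_screen(
    values: pd.Series, env: pd.DataFrame, variables, n_slices: int = 7
) -> list[SliceTest]:
    """slice_anova over several variables with BH-FDR adjustment across them."""
    tests = [slice_anova(values, env, v, n_slices) for v in variables]
    adj = fdr_adjust([t.kw_p for t in tests])
    for t, a in zip(tests, adj):
        t.fdr_p = float(a)
    return tests


def group_test(values: pd.Series, groups: pd.Series) -> dict:
    """Two-group comparison: group means with 95% CI and a two-sided
    Mann-Whitney U test (tie-corrected)."""
    common = values.index.intersection(groups.index)
    g = groups.loc[common]
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    a = values.loc[common][g == levels[0]].astype(float)
    b = values.loc[common][g == levels[1]].astype(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    out = {"p_value": float(res.pvalue), "U": float(res.statistic)}
    for name, arr in zip(levels, (a, b)):
        se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
        out[name] = {
            "mean": float(arr.mean()),
            "ci_low": float(arr.mean() - 1.96 * se),
            "ci_high": float(arr.mean() + 1.96 * se),
            "n": int(len(arr)),
        }
    return out


def endemism_profile(
    table: MOTUTable, pcrs: pd.DataFrame, site_of: pd.Series | dict
) -> pd.DataFrame:
    """Per-MOTU endemism: number of sites with presence and the maximum
    within-site mean relative frequency, sorted for plotting."""
    pcrs = validate_pcrs(pcrs)
    site_of = pd.Series(site_of)
    samples = pcrs[(pcrs["control_type"] == "sample") & pcrs["pcr_id"].isin(table.pcr_ids)]
    sites = samples["sample_id"].map(site_of)
    if sites.nunique() < 2:
        raise ValueError("need at least two sites")
    freq = table.relative_frequencies()[samples["pcr_id"].to_list()]
    site_mean = freq.T.groupby(sites.to_numpy()).mean().T  # MOTU x site
    n_sites = (site_mean > 0).sum(axis=1)
    out = pd.DataFrame(
        {"n_sites_present": n_sites, "max_site_frequency": site_mean.max(axis=1)}
    )
    return out.sort_values("max_site_frequency", ascending=False)


@dataclass
class TrendResult:
    """Linear trend of a class-abundance fraction against a variable."""

    fractions: pd.Series
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_excluded: int


def class_abundance_trend(
    table: MOTUTable,
    pcrs: pd.DataFrame,
    env: pd.DataFrame,
    class_a: str,
    class_b: str,
    variable: str,
) -> TrendResult:
    """Per-sample fraction of ``class_a`` reads among (a + b) reads, with its
    least-squares linear trend against ``variable``."""
    pcrs = validate_pcrs(pcrs)
    if "class" not in table.annotations.columns:
        raise ValueError("MOTU table has no class annotation")
    cls = table.annotations["class"]
    in_a, in_b = cls == class_a, cls == class_b
    if not in_a.any() or not in_b.any():
        raise ValueError("both classes must be present in the table")
    samples = pcrs[(pcrs["control_type"] == "sample") & pcrs["pcr_id"].isin(table.pcr_ids)]
    per_sample = table.counts[samples["pcr_id"].to_list()].T.groupby(
        samples.set_index("pcr_id")["sample_id"].to_dict()
    ).sum()  # sample x MOTU
    reads_a = per_sample.loc[:, in_a.to_numpy()].sum(axis=1)
    reads_b = per_sample.loc[:, in_b.to_numpy()].sum(axis=1)
    denom = reads_a + reads_b
    ok = denom > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("%d sample(s) without reads in either class excluded", n_excluded)
    frac = (reads_a[ok] / denom[ok]).astype(float)
    x = env.loc[frac.index, variable].astype(float)
    if frac.nunique() <= 1 or x.nunique() <= 1:
        return TrendResult(frac, 0.0, float(frac.mean()), 0.0, 1.0, n_excluded)
    fit = stats.linregress(x, frac)
    return TrendResult(
        frac,
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.pvalue),
        n_excluded,
    )
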