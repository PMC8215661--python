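"""MOTU-table quality control.

The filtering chain, in order: amplicon length bounds, rare-variant removal,
target-clade restriction, negative-control contaminant removal, failed-PCR
rejection, replicate-outlier detection, and finally aggregation of PCR
replicates into a sample x MOTU relative-frequency matrix.

Conventions follow the field defaults for these markers: length bounds
65-200 bp (Chlo01/Euka03) and 65-130 bp (Chlo02), both inclusive; a MOTU must
exceed 10 reads in at least one PCR; a PCR must total at least 200 reads
(Chlo01/Chlo02) or 1,000 (Euka03) to count as successful.  The read-count
threshold is applied as a minimum — a PCR below it is unreliable and dropped;
`direction="above"` inverts this for anyone wanting the literal opposite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import MOTUTable, QCReport, validate_pcrs

#: Inclusive amplicon length bounds per marker (bp).
LENGTH_BOUNDS = {"Chlo01": (65, 200), "Euka03": (65, 200), "Chlo02": (65, 130)}

#: Minimum total reads for a successful PCR, per marker.
MIN_PCR_READS = {"Chlo01": 200, "Chlo02": 200, "Euka03": 1000}

#: Default target clade per marker.
TARGET_CLADE = {"Chlo01": "Chlorophyta", "Chlo02": "Chlorophyceae", "Euka03": "Eukaryota"}

NEGATIVE_CONTROLS = ("extraction_blank", "pcr_blank")


def filter_length(
    table: MOTUTable,
    min_bp: int | None = None,
    max_bp: int | None = None,
    marker: str = "Chlo01",
) -> tuple[MOTUTable, QCReport]:
    """Remove MOTUs whose amplicon length falls outside [min_bp, max_bp]
    (bounds inclusive; defaults per marker)."""
    if min_bp is None or max_bp is None:
        dmin, dmax = LENGTH_BOUNDS[marker]
        min_bp = dmin if min_bp is None else min_bp
        max_bp = dmax if max_bp is None else max_bp
    if min_bp > max_bp:
        raise ValueError("min_bp must not exceed max_bp")
    if "length" not in table.annotations.columns:
        raise ValueError("MOTU table has no length information")
    lengths = table.annotations["length"]
    if lengths.isna().any():
        raise ValueError("MOTU table has missing length values")
    keep = (lengths >= min_bp) & (lengths <= max_bp)
    out = table.subset_motus(table.motu_ids[keep])
    report = QCReport(
        stage="length",
        motus_removed=int((~keep).sum()),
        reads_removed=table.total_reads - out.total_reads,
        details={"removed": list(table.motu_ids[~keep])},
    )
    return out, report


def filter_rare(table: MOTUTable, min_peak_reads: int = 10) -> tuple[MOTUTable, QCReport]:
    """Remove MOTUs never represented by more than ``min_peak_reads`` reads in
    any single PCR (strict: a peak equal to the threshold is removed)."""
    peaks = table.counts.max(axis=1)
    keep = peaks > min_peak_reads
    out = table.subset_motus(table.motu_ids[keep])
    report = QCReport(
        stage="rare",
        motus_removed=int((~keep).sum()),
        reads_removed=table.total_reads - out.total_reads,
        details={"removed": list(table.motu_ids[~keep])},
    )
    return out, report


def restrict_clade(table: MOTUTable, clade: str) -> tuple[MOTUTable, QCReport]:
    """Keep only MOTUs whose clade path contains ``clade`` (ancestor
    membership counts: a Chlorophyceae MOTU is inside Chlorophyta)."""
    if "clade_path" not in table.annotations.columns:
        raise ValueError("MOTU table has no taxonomy (clade_path) annotation")
    paths = table.annotations["clade_path"].fillna("")
    keep = paths.map(lambda p: clade in str(p).split(";"))
    out = table.subset_motus(table.motu_ids[keep])
    report = QCReport(
        stage="clade",
        motus_removed=int((~keep).sum()),
        reads_removed=table.total_reads - out.total_reads,
        details={"clade": clade, "removed": list(table.motu_ids[~keep])},
    )
    return out, report


def remove_contaminants(
    table: MOTUTable, pcrs: pd.DataFrame, metric: str = "rel_freq"
) -> tuple[MOTUTable, QCReport]:
    """Remove MOTUs more abundant in a negative control than in any sample.

    Abundance is compared as within-PCR relative frequency by default (read
    depths differ greatly between blanks and samples); ``metric="raw_reads"``
    compares raw counts.  Positive controls take part on neither side.
    """
    if metric not in ("rel_freq", "raw_reads"):
        raise ValueError(f"unknown metric {metric!r}")
    pcrs = validate_pcrs(pcrs)
    by_type = pcrs.set_index("pcr_id")["control_type"]
    cols = table.pcr_ids
    neg_cols = [c for c in cols if by_type.get(c) in NEGATIVE_CONTROLS]
    sample_cols = [c for c in cols if by_type.get(c) == "sample"]
    if not neg_cols:
        warnings.warn("no negative controls present; contaminant filter skipped")
        return table, QCReport(stage="contaminants", details={"skipped": "no negative controls"})

    data = table.relative_frequencies() if metric == "rel_freq" else table.counts
    neg_max = data[neg_cols].max(axis=1)
    sample_max = (
        data[sample_cols].max(axis=1) if sample_cols else pd.Series(0.0, index=table.motu_ids)
    )
    remove = neg_max > sample_max
    out = table.subset_motus(table.motu_ids[~remove])
    report = QCReport(
        stage="contaminants",
        motus_removed=int(remove.sum()),
        reads_removed=table.total_reads - out.total_reads,
        details={"metric": metric, "removed": list(table.motu_ids[remove])},
    )
    return out, report


def reject_failed_pcrs(
    table: MOTUTable,
    pcrs: pd.DataFrame,
    min_reads: int | None = None,
    direction: str = "below",
) -> tuple[MOTUTable, pd.DataFrame, QCReport]:
    """Drop unsuccessful PCRs from the table and metadata.

    A PCR fails when its total reads fall below the marker's minimum
    (inclusive retention: a total equal to the threshold passes).  Thresholds
    default per marker from :data:`MIN_PCR_READS`.
    """
    pcrs = validate_pcrs(pcrs)
    in_table = pcrs[pcrs["pcr_id"].isin(table.pcr_ids)].copy()
    totals = table.counts.sum(axis=0)
    thresholds = in_table["marker"].map(
        lambda m: min_reads if min_reads is not None else MIN_PCR_READS[m]
    )
    tot = totals.loc[in_table["pcr_id"]].to_numpy()
    if direction == "below":
        ok = tot >= thresholds.to_numpy()
    elif direction == "above":
        ok = tot <= thresholds.to_numpy()
    else:
        raise ValueError("direction must be 'below' or 'above'")
    if not ok.any():
        raise ValueError(
            "all PCRs rejected as failed; check thresholds "
            f"(totals ranged {tot.min()}-{tot.max()})"
        )
    kept_ids = in_table.loc[ok, "pcr_id"]
    out = table.subset_pcrs(kept_ids)
    out_pcrs = in_table[ok].reset_index(drop=True)
    report = QCReport(
        stage="failed_pcrs",
        pcrs_removed=int((~ok).sum()),
        reads_removed=table.total_reads - out.total_reads,
        details={"removed": list(in_table.loc[~ok, "pcr_id"])},
    )
    return out, out_pcrs, report


def hellinger_profiles(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger-transform PCR read profiles (columns): square roots of the
    within-PCR relative frequencies."""
    totals = counts.sum(axis=0)
    rel = counts.div(totals.where(totals > 0, 1.0), axis=1)
    return np.sqrt(rel)


def replicate_outliers(
    table: MOTUTable,
    pcrs: pd.DataFrame,
    rule: str = "tukey",
    k: float = 1.5,
    quantile: float = 0.975,
) -> tuple[list, pd.Series]:
    """Flag replicate PCRs far from their sample's barycenter.

    Per sample, each replicate profile is Hellinger-transformed and its
    Euclidean distance to the unweighted mean (barycenter) of the sample's
    transformed replicates is computed.  Distances are pooled across samples;
    a replicate is flagged when its distance exceeds Q3 + k*IQR (``tukey``) or
    the pooled ``quantile`` (``quantile`` rule).

    Returns (flagged pcr ids, per-PCR distances).
    """
    if rule not in ("tukey", "quantile"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    pcrs = validate_pcrs(pcrs)
    samples = pcrs[(pcrs["control_type"] == "sample") & pcrs["pcr_id"].isin(table.pcr_ids)]
    H = hellinger_profiles(table.counts)
    dists: dict[str, float] = {}
    for sample_id, grp in samples.groupby("sample_id", sort=True):
        cols = grp["pcr_id"].to_list()
        if len(cols) < 2:
            warnings.warn(f"sample {sample_id} has a single replicate; skipped")
            continue
        sub = H[cols].to_numpy()
        bary = sub.mean(axis=1, keepdims=True)
        d = np.sqrt(((sub - bary) ** 2).sum(axis=0))
        for c, dc in zip(cols, d):
            dists[c] = float(dc)
    distances = pd.Series(dists, name="distance").sort_index()
    if distances.empty:
        return [], distances
    if rule == "tukey":
        q1, q3 = np.quantile(distances, [0.25, 0.75])
        fence = q3 + k * (q3 - q1)
    else:
        fence = float(np.quantile(distances, quantile))
    flagged = list(distances.index[distances > fence])
    return flagged, distances


def aggregate(
    table: MOTUTable, pcrs: pd.DataFrame, drop_pcrs: list | None = None
) -> pd.DataFrame:
    """Aggregate retained sample replicates into a sample x MOTU matrix of
    relative frequencies (mean of replicate frequency vectors, renormalised).

    Samples with no retained replicate are dropped.
    """
    if table.n_motus == 0:
        raise ValueError("cannot aggregate an empty MOTU table")
    pcrs = validate_pcrs(pcrs)
    dropped = set(drop_pcrs or [])
    samples = pcrs[
        (pcrs["control_type"] == "sample")
        & pcrs["pcr_id"].isin(table.pcr_ids)
        & ~pcrs["pcr_id"].isin(dropped)
    ]
    freq = table.relative_frequencies()
    rows = {}
    for sample_id, grp in samples.groupby("sample_id", sort=True):
        sub = freq[grp["pcr_id"].to_list()]
        mean = sub.mean(axis=1)
        total = mean.sum()
        if total <= 0:
            continue
        rows[sample_id] = mean / total
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    out.columns.name = "motu_id"
    return out


def run_qc(
    table: MOTUTable,
    pcrs: pd.DataFrame,
    marker: str = "Chlo01",
    clade: str | None = None,
    min_reads: int | None = None,
    contaminant_metric: str = "rel_freq",
    fence_k: float = 1.5,
) -> tuple[pd.DataFrame, MOTUTable, pd.DataFrame, list[QCReport]]:
    """Full QC chain in the canonical order; returns the aggregated community
    matrix, the filtered table/metadata and all stage reports."""
    clade = clade if clade is not None else TARGET_CLADE[marker]
    reports: list[QCReport] = []
    table, rep = filter_length(table, marker=marker)
    reports.append(rep)
    table, rep = filter_rare(table)
    reports.append(rep)
    table, rep = restrict_clade(table, clade)
    reports.append(rep)
    table, rep = remove_contaminants(table, pcrs, metric=contaminant_metric)
    reports.append(rep)
    table, pcrs, rep = reject_failed_pcrs(table, pcrs, min_reads=min_reads)
    reports.append(rep)
    flagged, distances = replicate_outliers(table, pcrs, k=fence_k)
    reports.append(
        QCReport(
            stage="replicate_outliers",
            pcrs_removed=len(flagged),
            details={"flagged": flagged, "distances": distances},
        )
    )
    community = aggregate(table, pcrs, drop_pcrs=flagged)
    return community, table, pcrs, reports
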