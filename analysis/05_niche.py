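#!/usr/bin/env python
"""Niche inference for the identified taxa.

Runs the OMI decomposition with the dual permutation criterion for
specialization, derives each taxon's optimal elevational range, compares the
recovered optima with the generator's ground truth, and summarises the
specialized taxa by a PCA of their niche centres with a class contrast.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from alpzone import niche as nh
from alpzone.tables import read_env_table, read_motu_table, read_pcr_table

ENV_VARS = ["Elevation", "pH", "Nitrogen", "C_N_ratio", "FDD", "CWD", "DTR"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out / "data"
    community = pd.read_csv(data / "community.csv", index_col=0)
    env = read_env_table(data / "env.csv").loc[community.index]
    truth = pd.read_csv(data / "true_niches.csv", index_col="taxon_id")
    pcrs = read_pcr_table(data / "pcrs_retained.csv")
    table = read_motu_table(data / "motus_filtered.tsv", pcr_ids=pcrs["pcr_id"])

    rng = np.random.default_rng(args.seed)
    summary = nh.specialization_test(
        community, env, ENV_VARS, n_perm=args.n_perm, seed=rng
    )
    spec = summary.index[summary["specialized"]]
    print(f"{len(spec)}/{len(summary)} taxa specialized "
          f"(dual criterion, {args.n_perm} permutations)")

    known = summary.index.intersection(truth.index)
    sens = summary.loc[
        [t for t in known if not truth.loc[t, "generalist"]], "specialized"
    ].mean()
    fpr = summary.loc[
        [t for t in known if truth.loc[t, "generalist"]], "specialized"
    ].mean()
    print(f"vs ground truth: specialist sensitivity = {sens:.2f}, "
          f"generalist flag rate = {fpr:.2f}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranges = nh.optimal_ranges(community, env, ENV_VARS, taxa=summary.index)
    elev = ranges[ranges["variable"] == "Elevation"].set_index("taxon")
    both = elev.join(truth["opt_Elevation"], how="inner").dropna(subset=["opt_Elevation"])
    in_range = both[
        ~truth.loc[both.index, "generalist"]
        & both["opt_Elevation"].between(1250, 2940)
    ]
    err = (in_range["peak"] - in_range["opt_Elevation"]).abs()
    print(f"elevational optimum recovery (in-range specialists): "
          f"median error {err.median():.0f} m, {100 * (err <= 100).mean():.0f}% within 100 m")

    out_json = {
        "n_specialized": int(len(spec)),
        "sensitivity": float(sens),
        "generalist_flag_rate": float(fpr),
        "median_optimum_error_m": float(err.median()),
    }
    if len(spec) >= 3:
        centers = ranges[ranges["taxon"].isin(spec)].pivot(
            index="taxon", columns="variable", values="center"
        )
        classes = table.annotations["class"].reindex(centers.index)
        pca = nh.niche_pca(centers, classes,
                           class_pair=("Trebouxiophyceae", "Chlorophyceae"))
        print(f"niche-centre PCA: axes carry "
              + ", ".join(f"{v:.1f}%" for v in pca.percent_variance[:2])
              + f" of the variance; class contrast on axis 1: "
              f"Mann-Whitney p = {pca.mw_p if pca.mw_p is None else round(pca.mw_p, 4)}")
        pca.scores.to_csv(args.out / "niche_pca_scores.csv")
        out_json["pca_percent_variance"] = [float(v) for v in pca.percent_variance[:2]]
        out_json["class_contrast_p"] = pca.mw_p

    summary.to_csv(args.out / "niche_summary.csv")
    ranges.to_csv(args.out / "optimal_ranges.csv", index=False)
    (args.out / "niche_summary.json").write_text(
        json.dumps(out_json, indent=2, sort_keys=True)
    )


if __name__ == "__main__":
    main()
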