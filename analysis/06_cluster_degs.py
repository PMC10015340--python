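#!/usr/bin/env python
"""Cluster the factor-responsive genes by expression mode.

For each dataset and factor category: apply the factor's |log2FC| screen,
z-score the 12-cell mean profiles, pick k by the 75% between-cluster-SS
rule, cluster with k-means, and t-test all cluster pairs on the MD-vs-SD
summary.  Writes membership and contrast tables.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
IN_EXPR = ROOT / "results" / "expression"
IN_DEG = ROOT / "results" / "degs"
OUT = ROOT / "results" / "clusters"


def cell_profiles(fpkm, design):
    cells = design.table.groupby(["stage", "tod"], sort=False)["sample"] \
        .apply(list)
    return pd.DataFrame({f"{s}-{t}": np.log2(fpkm[cols] + 1).mean(axis=1)
                         for (s, t), cols in cells.items()})


def main(seed: int = 1) -> None:
    from lysiomics import io
    from lysiomics.cluster import (cluster_degs, contrast_clusters,
                                   screen_by_fold_change, select_k)

    OUT.mkdir(parents=True, exist_ok=True)
    if not (IN_DEG / "conservative_factorial_screen.tsv").exists():
        raise SystemExit("run 05_differential_expression.py first")

    for name in ("conservative", "profligate"):
        fpkm = io.read_expression_tsv(IN_EXPR / f"{name}_fpkm.tsv")
        design = io.read_design_tsv(IN_EXPR / f"{name}_design.tsv")
        screen = pd.read_csv(IN_DEG / f"{name}_factorial_screen.tsv", sep="\t")
        profiles = cell_profiles(fpkm, design)

        members_all, contrasts_all = [], []
        for factor in ("drought", "TOD", "interaction"):
            genes = screen_by_fold_change(screen, factor)
            if len(genes) < 4:
                print(f"{name}/{factor}: only {len(genes)} genes, skipped")
                continue
            prof = profiles.loc[genes]
            k, reached = select_k(prof, range(1, min(26, len(genes))),
                                  seed=seed)
            cs = cluster_degs(prof, k, seed=seed, factor=factor)
            members_all.append(pd.DataFrame({
                "gene": prof.index, "factor": factor,
                "cluster": cs.assignments.values,
                "between_ss_ratio": cs.between_ss_ratio,
                "threshold_reached": reached}))
            for a in range(k):
                for b in range(a + 1, k):
                    pa = prof[cs.assignments == a]
                    pb = prof[cs.assignments == b]
                    if len(pa) < 2 or len(pb) < 2:
                        continue
                    r = contrast_clusters(pa, pb, labels=(a, b))
                    contrasts_all.append({
                        "factor": factor, "cluster_a": a, "cluster_b": b,
                        "t": round(r.t_statistic, 2), "p": r.p_value,
                        "significant": r.significant})
            print(f"{name}/{factor}: {len(genes)} genes -> k={k} "
                  f"(ratio reached: {reached})")
        pd.concat(members_all).to_csv(OUT / f"{name}_clusters.tsv",
                                      sep="\t", index=False)
        pd.DataFrame(contrasts_all).to_csv(OUT / f"{name}_contrasts.tsv",
                                           sep="\t", index=False)
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
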