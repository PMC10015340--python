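#!/usr/bin/env python
"""Co-expression modules, hub genes, cross-species links, lasso network.

For each dataset: build the unsigned TOM (beta = 10) on replicate-averaged
log FPKM of the screened genes, detect modules (min size 30, merge height
0.25), associate eigengenes with the transpiration trait, call hub genes
(kME >= 0.85, |GS| >= 0.85), and infer the signed inter-modular lasso
network.  Finally correlate eigengenes across the two datasets.  Writes
membership, eigengene, gene-statistic and edge tables (TSV + GraphML).
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
IN_EXPR = ROOT / "results" / "expression"
OUT = ROOT / "results" / "network"


def main(seed: int = 1) -> None:
    from lysiomics import io
    from lysiomics.network import (build_network, cross_species_module_correlation,
                                   detect_modules, gene_statistics, hub_genes,
                                   intermodular_lasso, module_trait_association)
    sys.path.insert(0, str(Path(__file__).parent))
    import importlib
    cluster_mod = importlib.import_module("06_cluster_degs")

    OUT.mkdir(parents=True, exist_ok=True)
    if not (IN_EXPR / "conservative_fpkm.tsv").exists():
        raise SystemExit("run 04_simulate_counts.py first")

    mes_by_dataset = {}
    for name in ("conservative", "profligate"):
        fpkm = io.read_expression_tsv(IN_EXPR / f"{name}_fpkm.tsv")
        design = io.read_design_tsv(IN_EXPR / f"{name}_design.tsv")
        trait = np.loadtxt(IN_EXPR / f"{name}_trait.tsv")
        profiles = cluster_mod.cell_profiles(fpkm, design)
        # restrict to variable genes (network over DEG-like set)
        var = profiles.var(axis=1)
        data = profiles.loc[var.sort_values(ascending=False).index[:800]]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_network(data, beta=10.0)
            mods = detect_modules(net, data)
        mods.labels.rename("module").to_csv(OUT / f"{name}_modules.tsv", sep="\t")
        mods.eigengenes.to_csv(OUT / f"{name}_eigengenes.tsv", sep="\t")
        assoc = module_trait_association(mods.eigengenes, trait)
        assoc.to_csv(OUT / f"{name}_trait_association.tsv", sep="\t", index=False)
        gs = gene_statistics(data, mods.labels, mods.eigengenes, trait)
        hubs = hub_genes(gs.table, assoc)
        gs.table.assign(hub=gs.table.index.isin(hubs)) \
            .to_csv(OUT / f"{name}_gene_stats.tsv", sep="\t")
        sig = assoc[assoc.significant]
        print(f"{name}: {mods.labels.max()} modules "
              f"({(mods.labels == 0).sum()} genes unassigned); "
              f"{len(sig)} trait-associated (P<0.01); {len(hubs)} hub genes")

        if mods.eigengenes.shape[1] >= 3:
            lasso_net = intermodular_lasso(mods.eigengenes)
            lasso_net.edges.to_csv(OUT / f"{name}_intermodular_edges.tsv",
                                   sep="\t", index=False)
            try:
                import networkx as nx
                g = nx.DiGraph()
                for _, e in lasso_net.edges.iterrows():
                    g.add_edge(e.source, e.target,
                               weight=float(e.coefficient), sign=int(e.sign))
                nx.write_graphml(g, OUT / f"{name}_intermodular.graphml")
            except ImportError:
                pass
            print(f"  inter-modular lasso edges: {len(lasso_net.edges)}")
        mes_by_dataset[name] = mods.eigengenes

    cross = cross_species_module_correlation(mes_by_dataset["conservative"],
                                             mes_by_dataset["profligate"])
    cross.to_csv(OUT / "cross_dataset_me_correlation.tsv", sep="\t", index=False)
    top = cross.loc[cross.p_value.idxmin()]
    print(f"cross-dataset MEs: strongest pair {top.module_a}~{top.module_b} "
          f"r={top.pearson_r:.3f} P={top.p_value:.2e}")
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
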