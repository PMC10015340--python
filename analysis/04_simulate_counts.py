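#!/usr/bin/env python
"""Simulate the RNA-seq count matrices for both species-like datasets.

Two independent draws of the NB count simulator (different seeds and gene
complements) stand in for the two species.  The trait-linked module is
driven by the transpiration trait vector computed from the corresponding
lysimeter simulation, so the co-expression stage has a physiological
anchor.  Counts, FPKM, design and truth tables are written as TSV.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "expression"

SPECIES_SEEDS = {"conservative": 101, "profligate": 202}


def main(seed: int = 1) -> None:
    from lysiomics import io
    from lysiomics.pipeline import condition_trait_vector
    from lysiomics.presets import species_presets
    from lysiomics.simulate import (ExpressionSimSpec, simulate_counts,
                                    simulate_environment, simulate_pair)

    OUT.mkdir(parents=True, exist_ok=True)
    presets = species_presets()
    for name, sp_seed in SPECIES_SEEDS.items():
        env = simulate_environment(28, seed=seed)
        _, treated = simulate_pair(presets[name], env, seed=seed)
        trait = condition_trait_vector(treated)
        spec = ExpressionSimSpec(n_genes=2000, trait=trait,
                                 seed=seed * 1000 + sp_seed)
        counts, fpkm, design, truth = simulate_counts(spec)
        io.write_expression_tsv(counts, OUT / f"{name}_counts.tsv")
        io.write_expression_tsv(fpkm, OUT / f"{name}_fpkm.tsv")
        io.write_design_tsv(design, OUT / f"{name}_design.tsv")
        truth["effects"].to_csv(OUT / f"{name}_truth_effects.tsv",
                                sep="\t", index=False)
        truth["modules"].to_csv(OUT / f"{name}_truth_modules.tsv",
                                sep="\t", index=False)
        import numpy as np
        np.savetxt(OUT / f"{name}_trait.tsv", trait, fmt="%.6f")
        print(f"{name}: {counts.shape[0]} genes x {counts.shape[1]} samples, "
              f"{len(truth['effects'])} planted effects, "
              f"{truth['modules'].module.nunique()} modules")
    print(f"matrices written under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
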