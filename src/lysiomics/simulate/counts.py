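"""Negative-binomial RNA-seq count simulator for the 4-stage x 3-TOD design.

Counts are drawn gene-by-sample from NB(mean, phi) where the log mean is a
baseline plus planted drought / time-of-day / interaction effects plus
module latent factors, scaled by library size.  FPKM is derived from the
counts, gene lengths and library sizes, so pairwise (FPKM-based) and
GLM (count-based) analyses run on the same dataset.  Truth tables record
the planted differentially expressed genes and module memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("WW", "MD", "SD", "RC")
TODS = (6, 12, 16)


@dataclass
class SampleDesign:
    """Sample table: stage x time-of-day x replicate."""

    table: pd.DataFrame  # columns: sample, stage, tod, replicate

    @classmethod
    def full_factorial(cls, replicates: int = 3) -> "SampleDesign":
        rows = [
            {"sample": f"{s}-{t}-r{r}", "stage": s, "tod": t, "replicate": r}
            for s in STAGES for t in TODS for r in range(1, replicates + 1)
        ]
        return cls(pd.DataFrame(rows))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def cell_labels(self) -> list[str]:
        """The 12 stage x TOD condition labels in canonical order."""
        return [f"{s}-{t}" for s in STAGES for t in TODS]


@dataclass
class ExpressionSimSpec:
    """Parameters of the count simulator.

    ``module_sizes`` are disjoint blocks of co-regulated genes driven by
    latent 12-vectors (one value per stage x TOD cell); the first module's
    factor is the supplied ``trait`` vector (standardized), tying it to
    transpiration.  ``n_de_*`` genes get planted effects of the stated
    log2 magnitude.
    """

    n_genes: int = 2000
    replicates: int = 3
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion_log_mean: float = np.log(0.1)
    dispersion_log_sd: float = 0.5
    n_de_drought: int = 100
    lfc_drought: float = 2.0
    n_de_tod: int = 60
    lfc_tod: float = 1.5
    n_de_interaction: int = 40
    lfc_interaction: float = 1.5
    module_sizes: tuple = (60, 50, 40)
    module_loading_sd: float = 0.25
    module_scale: float = 0.8
    trait: np.ndarray | None = None
    mean_library_size: float = 1.0e7
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.replicates < 2:
            raise ValueError("need n_genes > 0 and >= 2 replicates")
        if any(m < 30 for m in self.module_sizes):
            raise ValueError("module sizes must be >= 30")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("modules exceed gene count")
        if self.trait is not None and len(np.asarray(self.trait)) != 12:
            raise ValueError("trait vector must have length 12 (stage x TOD)")


def _default_trait() -> np.ndarray:
    """Stylized per-cell mean transpiration: diurnal course x stage level."""
    tod_profile = np.array([0.2, 1.0, 0.6])
    stage_level = np.array([1.0, 0.7, 0.25, 0.8])
    return np.outer(stage_level, tod_profile).ravel()


def simulate_counts(spec: ExpressionSimSpec):
    """Draw counts, FPKM and truth tables for the factorial design.

    Returns ``(counts, fpkm, design, truth)`` where ``counts``/``fpkm`` are
    gene x sample DataFrames and ``truth`` is a dict of DataFrames
    (``effects`` per planted gene/factor, ``modules`` membership) plus the
    per-gene dispersions, lengths and library sizes used.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    design = SampleDesign.full_factorial(spec.replicates)
    n_samples = len(design.samples)
    genes = np.array([f"g{i:05d}" for i in range(spec.n_genes)])

    base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    phi = rng.lognormal(spec.dispersion_log_mean, spec.dispersion_log_sd, spec.n_genes)
    lengths = rng.integers(500, 5000, spec.n_genes)
    libsizes = rng.lognormal(np.log(spec.mean_library_size), 0.1, n_samples)

    stage_idx = design.table["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
    tod_idx = design.table["tod"].map({t: i for i, t in enumerate(TODS)}).to_numpy()
    cell_idx = stage_idx * len(TODS) + tod_idx  # 0..11

    # Disjoint gene sets: modules first, then DE sets drawn from the rest
    # (DE sets may overlap each other; overlaps are recorded in the truth).
    cursor = 0
    module_members: list[np.ndarray] = []
    for size in spec.module_sizes:
        module_members.append(np.arange(cursor, cursor + size))
        cursor += size
    free = np.arange(cursor, spec.n_genes)
    de_drought = rng.choice(free, size=min(spec.n_de_drought, free.size), replace=False)
    de_tod = rng.choice(free, size=min(spec.n_de_tod, free.size), replace=False)
    de_inter = rng.choice(free, size=min(spec.n_de_interaction, free.size), replace=False)

    log_mu = np.tile(base[:, None], (1, n_samples))

    # Drought main effect: stage-dependent shift, max |log2FC| = lfc_drought.
    stage_shape = np.array([0.0, 0.6, 1.0, 0.3])
    sign = rng.choice([-1.0, 1.0], size=de_drought.size)
    log_mu[de_drought] += (np.log(2.0) * spec.lfc_drought
                           * sign[:, None] * stage_shape[stage_idx][None, :])

    # TOD effect: sinusoidal diurnal profile with random phase.
    phase = rng.uniform(0, 2 * np.pi, size=de_tod.size)
    hours = np.array(TODS, dtype=float)[tod_idx]
    diurnal = np.cos(2 * np.pi * hours[None, :] / 24.0 - phase[:, None])
    log_mu[de_tod] += np.log(2.0) * spec.lfc_tod * diurnal / 2.0

    # Interaction: stage-specific midday multiplier (MD at noon).
    inter_mask = ((stage_idx == 1) & (tod_idx == 1)).astype(float)
    sign_i = rng.choice([-1.0, 1.0], size=de_inter.size)
    log_mu[de_inter] += np.log(2.0) * spec.lfc_interaction * sign_i[:, None] * inter_mask[None, :]

    # Module latent factors: per-cell latent value broadcast to replicates.
    trait = np.asarray(spec.trait, dtype=float) if spec.trait is not None else _default_trait()
    factors = []
    for m in range(len(spec.module_sizes)):
        if m == 0:
            f = trait.copy()
        else:
            f = rng.normal(0.0, 1.0, 12)
        f = (f - f.mean()) / f.std()
        factors.append(f)
    loadings = {}
    for m, members in enumerate(module_members):
        load = 1.0 + rng.normal(0.0, spec.module_loading_sd, members.size)
        loadings[m] = load
        log_mu[members] += spec.module_scale * load[:, None] * factors[m][cell_idx][None, :]

    mu = np.exp(log_mu) * (libsizes / spec.mean_library_size)[None, :]
    # NB draw via gamma-Poisson mixture: shape 1/phi, scale mu*phi.
    shape = (1.0 / phi)[:, None]
    lam = rng.gamma(shape, mu * phi[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes, columns=design.samples)
    from ..degs import fpkm as _fpkm
    fpkm_df = _fpkm(counts_df, pd.Series(lengths, index=genes),
                    pd.Series(libsizes, index=design.samples))

    effects = []
    for gset, factor, lfc in ((de_drought, "drought", spec.lfc_drought),
                              (de_tod, "TOD", spec.lfc_tod),
                              (de_inter, "interaction", spec.lfc_interaction)):
        for g in gset:
            effects.append({"gene": genes[g], "factor": factor, "planted_lfc": lfc})
    modules_truth = []
    for m, members in enumerate(module_members):
        for j, g in enumerate(members):
            modules_truth.append({"gene": genes[g], "module": m,
                                  "loading": loadings[m][j],
                                  "trait_linked": m == 0})
    truth = {
        "effects": pd.DataFrame(effects),
        "modules": pd.DataFrame(modules_truth),
        "dispersion": pd.Series(phi, index=genes, name="phi"),
        "gene_lengths": pd.Series(lengths, index=genes, name="length_bp"),
        "library_sizes": pd.Series(libsizes, index=design.samples, name="libsize"),
        "factors": np.array(factors),
        "trait": trait,
    }
    return counts_df, fpkm_df, design, truth
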