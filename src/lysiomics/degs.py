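"""Differential expression: pairwise DEG filters and the factorial NB screen.

Two routes, as in time-series drought RNA-seq practice:

* ``pairwise_deg`` compares two stage conditions sampled at the same time
  of day.  Genes must pass an expression filter (FPKM >= 1 in every
  replicate of at least one condition) and a variability filter
  (CV < 0.2 within each passing condition); surviving genes are tested
  with a negative-binomial likelihood-ratio test on counts, and a DEG
  calls for |log2FC| >= 1 and BH q <= 0.05.

* ``factorial_glm_screen`` fits, per gene, a negative-binomial log-linear
  model over the full 4-stage x 3-TOD design (library-size offset) and
  performs three nested likelihood-ratio tests: interaction (full vs
  additive), drought main effect (additive vs TOD-only) and TOD main
  effect (additive vs drought-only), with BH-FDR within each factor
  family.

Dispersions are per-gene method-of-moments estimates shrunk toward a
smooth mean-dispersion trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import DomainWarning

from .simulate.counts import STAGES, TODS, SampleDesign

PHI_FLOOR = 1e-8


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample normalization factors.

    Robust to differentially expressed genes, unlike raw column sums whose
    composition shifts with the conditions.  Factors are scaled to
    geometric mean 1.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    ok = np.isfinite(logs).all(axis=1)
    if not ok.any():
        raise ValueError("no gene expressed in all samples")
    ref = logs[ok].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs[ok] - ref, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (library size/1e6))."""
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def estimate_dispersion(
    counts: pd.DataFrame,
    design: SampleDesign,
    shrinkage: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion phi, moment-matched then trend-shrunk.

    Within each stage x TOD cell the NB model gives var = mu + phi mu^2;
    pooling (var_c - mean_c) over cells against mean_c^2 yields the raw
    moment estimate.  Raw estimates are shrunk with weight ``shrinkage``
    toward a running-median trend of phi against mean expression, and
    floored at 1e-8.
    """
    cells = design.table.groupby(["stage", "tod"], sort=False)["sample"].apply(list)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for samples in cells:
        sub = counts[samples].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.clip(raw, PHI_FLOOR, None)

    mean_expr = counts.to_numpy(dtype=float).mean(axis=1)
    order = np.argsort(mean_expr)
    half = max(10, len(raw) // 20)
    trend_sorted = pd.Series(raw[order]).rolling(2 * half + 1, center=True,
                                                 min_periods=1).median().to_numpy()
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted
    shrunk = np.clip((1 - shrinkage) * raw + shrinkage * trend, PHI_FLOOR, None)
    return pd.Series(shrunk, index=counts.index, name="phi")


def _nb_llf(y: np.ndarray, X: np.ndarray, phi: float,
            offset: np.ndarray) -> float:
    """Log-likelihood of the NB GLM fit of y on X (log link, fixed phi)."""
    fam = sm.families.NegativeBinomial(alpha=max(phi, PHI_FLOOR))
    model = sm.GLM(y, X, family=fam, offset=offset)
    res = model.fit(maxiter=100, tol=1e-9)
    return float(res.llf)


def _lrt(y, X_full, X_red, phi, offset) -> tuple[float, float, int]:
    ll_full = _nb_llf(y, X_full, phi, offset)
    ll_red = _nb_llf(y, X_red, phi, offset)
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    df = X_full.shape[1] - X_red.shape[1]
    return stat, stats.chi2.sf(stat, df), df


@dataclass
class DegRecord:
    gene: str
    comparison: str
    log2_fc: float
    p_value: float
    q_value: float
    passed_expression_filter: bool
    passed_cv_filter: bool
    is_deg: bool


def pairwise_deg(
    counts: pd.DataFrame,
    fpkm_matrix: pd.DataFrame,
    design: SampleDesign,
    condition_a: tuple,
    condition_b: tuple,
    fpkm_min: float = 1.0,
    cv_max: float = 0.2,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """DEG call between two (stage, TOD) conditions sharing a time of day.

    Returns one row per gene with the filter flags, log2 fold change
    (condition_b over condition_a, pseudocount 1 FPKM), NB-LRT p, BH q
    across tested genes, and the final DEG flag.
    """
    (stage_a, tod_a), (stage_b, tod_b) = condition_a, condition_b
    if tod_a != tod_b:
        raise ValueError("pairwise comparisons must share the time of day")
    tab = design.table
    samples_a = list(tab.loc[(tab.stage == stage_a) & (tab.tod == tod_a), "sample"])
    samples_b = list(tab.loc[(tab.stage == stage_b) & (tab.tod == tod_b), "sample"])
    if not samples_a or not samples_b:
        raise ValueError("unknown sample condition labels")
    if min(len(samples_a), len(samples_b)) < 2:
        raise ValueError("need >= 2 replicates per condition")

    fa = fpkm_matrix[samples_a].to_numpy(dtype=float)
    fb = fpkm_matrix[samples_b].to_numpy(dtype=float)
    expr_a = (fa >= fpkm_min).all(axis=1)
    expr_b = (fb >= fpkm_min).all(axis=1)
    passed_expr = expr_a | expr_b

    def _cv_ok(mat, active):
        m = mat.mean(axis=1)
        s = mat.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(m > 0, s / m, np.inf)
        return np.where(active, cv < cv_max, True)

    passed_cv = _cv_ok(fa, expr_a) & _cv_ok(fb, expr_b)
    tested = passed_expr & passed_cv

    lfc = np.log2((fb.mean(axis=1) + 1.0) / (fa.mean(axis=1) + 1.0))

    if dispersion is None:
        sub_design = SampleDesign(tab[tab["sample"].isin(samples_a + samples_b)]
                                  .reset_index(drop=True))
        dispersion = estimate_dispersion(counts[samples_a + samples_b], sub_design)
    phi = dispersion.reindex(counts.index).to_numpy()

    ya = counts[samples_a].to_numpy(dtype=float)
    yb = counts[samples_b].to_numpy(dtype=float)
    sf = size_factors(counts)
    offs = np.log(np.concatenate([sf[samples_a], sf[samples_b]]))
    group = np.concatenate([np.zeros(len(samples_a)), np.ones(len(samples_b))])
    X_full = np.column_stack([np.ones_like(group), group])
    X_red = np.ones((len(group), 1))

    pvals = np.full(len(counts), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        for i in np.where(tested)[0]:
            y = np.concatenate([ya[i], yb[i]])
            if y.sum() == 0:
                continue
            try:
                _, p, _ = _lrt(y, X_full, X_red, phi[i], offs)
            except Exception:
                p = np.nan
            pvals[i] = p

    qvals = np.full(len(counts), np.nan)
    done = np.isfinite(pvals)
    if done.any():
        qvals[done] = bh_adjust(pvals[done])

    comparison = f"{stage_b}-vs-{stage_a}@{tod_a}"
    out = pd.DataFrame({
        "gene": counts.index,
        "comparison": comparison,
        "log2_fc": lfc,
        "p_value": pvals,
        "q_value": qvals,
        "passed_expression_filter": passed_expr,
        "passed_cv_filter": passed_cv,
    })
    out["is_deg"] = (out.passed_expression_filter & out.passed_cv_filter
                     & (out.log2_fc.abs() >= lfc_min) & (out.q_value <= q_max))
    return out


def factorial_glm_screen(
    counts: pd.DataFrame,
    design: SampleDesign,
    alpha: float = 0.05,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Three-hypothesis NB-GLM screen over the full factorial design.

    Per gene the log mean is modelled on categorical drought stage (K),
    categorical time of day (T) and their interaction, with a log library
    size offset.  Likelihood-ratio tests: interaction = full vs additive;
    drought = additive vs TOD-only; TOD = additive vs drought-only.
    BH-FDR is applied within each factor family.  Returns a long table
    (gene x factor) with the LRT statistic, p, FDR, the factor's max
    |log2FC| contrast and the significance flag.
    """
    if not np.issubdtype(counts.to_numpy().dtype, np.integer):
        if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
            raise ValueError("factorial screen requires integer counts")
    tab = (design.table.set_index("sample").loc[counts.columns]
           .rename_axis("sample").reset_index())
    stage = pd.Categorical(tab["stage"], categories=list(STAGES))
    tod = pd.Categorical(tab["tod"].astype(int), categories=list(TODS))
    K = pd.get_dummies(stage, drop_first=True).to_numpy(dtype=float)
    T = pd.get_dummies(tod, drop_first=True).to_numpy(dtype=float)
    inter = np.einsum("ij,ik->ijk", K, T).reshape(len(tab), -1)
    ones = np.ones((len(tab), 1))
    X_full = np.hstack([ones, K, T, inter])
    X_add = np.hstack([ones, K, T])
    X_k = np.hstack([ones, K])
    X_t = np.hstack([ones, T])

    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    if dispersion is None:
        dispersion = estimate_dispersion(counts, design)
    phi = dispersion.reindex(counts.index).to_numpy()

    # normalized per-cell means for fold-change summaries
    cpm = counts.div(sf, axis=1)
    cell_means = np.column_stack([
        cpm[tab.loc[(tab.stage == s) & (tab.tod == t), "sample"]].mean(axis=1)
        for s in STAGES for t in TODS
    ])  # genes x 12 in canonical order
    log_cells = np.log2(cell_means + 1.0).reshape(len(counts), len(STAGES), len(TODS))
    stage_prof = log_cells.mean(axis=2)      # genes x stages
    tod_prof = log_cells.mean(axis=1)        # genes x tods
    grand = log_cells.mean(axis=(1, 2))
    lfc_drought = np.abs(stage_prof - stage_prof[:, [0]]).max(axis=1)
    lfc_tod = np.max(np.abs(tod_prof[:, :, None] - tod_prof[:, None, :]), axis=(1, 2))
    resid = (log_cells - stage_prof[:, :, None] - tod_prof[:, None, :]
             + grand[:, None, None])
    lfc_inter = np.abs(resid).max(axis=(1, 2))

    mats = counts.to_numpy(dtype=float)
    rows = []
    factor_contrasts = {"interaction": (X_full, X_add, lfc_inter),
                        "drought": (X_add, X_t, lfc_drought),
                        "TOD": (X_add, X_k, lfc_tod)}
    pcols = {f: np.full(len(counts), np.nan) for f in factor_contrasts}
    stat_cols = {f: np.full(len(counts), np.nan) for f in factor_contrasts}
    skipped = np.zeros(len(counts), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        for i in range(len(counts)):
            y = mats[i]
            if y.sum() == 0:
                skipped[i] = True
                continue
            for factor, (Xf, Xr, _) in factor_contrasts.items():
                try:
                    stat, p, _ = _lrt(y, Xf, Xr, phi[i], offset)
                except Exception:
                    stat, p = np.nan, np.nan
                stat_cols[factor][i] = stat
                pcols[factor][i] = p

    for factor, (_, _, lfc) in factor_contrasts.items():
        fdr = np.full(len(counts), np.nan)
        done = np.isfinite(pcols[factor])
        if done.any():
            fdr[done] = bh_adjust(pcols[factor][done])
        for i in range(len(counts)):
            rows.append({
                "gene": counts.index[i],
                "factor": factor,
                "lrt_statistic": stat_cols[factor][i],
                "p_value": pcols[factor][i],
                "fdr": fdr[i],
                "max_abs_log2_fc": float(lfc[i]),
                "significant": bool(np.isfinite(fdr[i]) and fdr[i] <= alpha),
                "skipped_all_zero": bool(skipped[i]),
            })
    return pd.DataFrame(rows)


def unique_deg_percentage(n_unique_degs: int, n_protein_coding: int) -> float:
    """Unique DEGs as a percentage of the protein-coding gene complement,
    rounded to one decimal (the convention used for reporting)."""
    return round(100.0 * n_unique_degs / n_protein_coding, 1)
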