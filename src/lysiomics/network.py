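"""Weighted co-expression network analysis and inter-modular inference.

Pipeline over a genes x 12-condition matrix (replicate-averaged,
log-transformed FPKM) with an aligned transpiration trait vector:

1. unsigned adjacency a_ij = |cor|^beta (beta = 10) and the topological
   overlap matrix (TOM);
2. average-linkage clustering of 1 - TOM, static tree cut with minimum
   module size 30, then merging of modules whose eigengenes are closer
   than the 0.25 dissimilarity height;
3. module eigengenes (first principal component, sign-oriented), Spearman
   module-trait association, per-gene kME/GS and the hub rule
   kME >= 0.85 & |GS| >= 0.85 inside trait-associated modules;
4. cross-species eigengene correlation (Pearson, t-based p at n = 12) and
   a lasso inter-modular network with lambda from leave-one-out CV and the
   one-standard-error rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.linear_model import lasso_path


@dataclass
class Network:
    genes: pd.Index
    adjacency: np.ndarray
    tom: np.ndarray
    beta: float

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


@dataclass
class ModuleSet:
    labels: pd.Series               # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame        # condition x module ("ME<k>")
    explained_variance: dict
    linkage: np.ndarray
    merge_record: list


@dataclass
class GeneStats:
    table: pd.DataFrame             # gene, module, kME, GS, hub


def build_network(data: pd.DataFrame, beta: float = 10.0) -> Network:
    """Unsigned adjacency |cor|^beta and TOM from a genes x condition matrix.

    Zero-variance genes are excluded with a warning.  TOM_ij =
    (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), diagonal 1.
    """
    if len(data) < 3:
        raise ValueError("need >= 3 genes to build a network")
    sd = data.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"excluding {(sd == 0).sum()} zero-variance genes")
        data = data[sd > 0]
    X = data.to_numpy(dtype=float)
    a = np.abs(np.corrcoef(X)) ** beta
    np.fill_diagonal(a, 1.0)
    tom = tom_from_adjacency(a)
    return Network(genes=data.index, adjacency=a, tom=tom, beta=beta)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal."""
    a0 = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a0) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    assert np.all(tom <= 1.0 + 1e-12) and np.allclose(np.diag(tom), 1.0)
    return tom


def module_eigengenes(data: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, dict]:
    """First principal component per module over gene-standardized profiles.

    Each ME is unit-norm over the 12 conditions, sign-oriented so that the
    average gene-ME correlation within the module is positive.  Returns the
    condition x module ME matrix and per-module explained variance.
    """
    mes = {}
    ev = {}
    for mod in sorted(set(labels) - {0}):
        genes = labels.index[labels == mod]
        if len(genes) < 2:
            raise ValueError(f"module {mod} smaller than 2 genes")
        sub = data.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (sub - mu) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        me = Vt[0]
        corr_sum = (Z @ me).sum()
        if corr_sum < 0:
            me = -me
        mes[f"ME{mod}"] = me
        ev[f"ME{mod}"] = float(S[0] ** 2 / (S ** 2).sum())
    me_df = pd.DataFrame(mes, index=data.columns)
    return me_df, ev


def detect_modules(
    net: Network,
    data: pd.DataFrame,
    min_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float = 0.9,
) -> ModuleSet:
    """Average-linkage tree cut of 1 - TOM with ME-based module merging.

    The dendrogram is cut at ``cut_height`` ("tree" variant of the dynamic
    cut: static height + minimum size); branches smaller than ``min_size``
    are left unassigned (label 0).  Modules whose eigengene dissimilarity
    1 - cor(ME_a, ME_b) falls below ``merge_height`` are merged, and
    eigengenes recomputed, until no pair is that close.
    """
    d = net.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(0, index=net.genes, dtype=int)
    next_id = 1
    for lab in np.unique(raw):
        members = net.genes[raw == lab]
        if len(members) >= min_size:
            labels.loc[members] = next_id
            next_id += 1

    merge_record = []
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        mes, _ = module_eigengenes(data.loc[labels.index], labels)
        cor = np.corrcoef(mes.to_numpy().T)
        diss = 1.0 - cor
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if diss[i, j] < merge_height and (best is None or diss[i, j] < best[0]):
                    best = (diss[i, j], mods[i], mods[j])
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
        merge_record.append((a, b))

    # relabel 1..n by decreasing size
    mods = sorted(set(labels) - {0},
                  key=lambda m: (-int((labels == m).sum()), m))
    remap = {old: new for new, old in enumerate(mods, start=1)}
    labels = labels.map(lambda m: remap.get(m, 0))
    mes, ev = (module_eigengenes(data, labels) if set(labels) - {0}
               else (pd.DataFrame(index=data.columns), {}))
    return ModuleSet(labels=labels, eigengenes=mes, explained_variance=ev,
                     linkage=Z, merge_record=merge_record)


def module_trait_association(mes: pd.DataFrame, trait: np.ndarray,
                             alpha: float = 0.01) -> pd.DataFrame:
    """Spearman rho and two-sided p of each module eigengene against the
    trait; constant eigengenes yield NaN with a degenerate flag."""
    trait = np.asarray(trait, dtype=float)
    if len(trait) != len(mes):
        raise ValueError("trait must align with the ME conditions")
    rows = []
    for col in mes.columns:
        me = mes[col].to_numpy()
        if np.ptp(me) == 0 or np.ptp(trait) == 0:
            rows.append({"module": col, "spearman_rho": np.nan,
                         "p_value": np.nan, "significant": False,
                         "degenerate": True})
            continue
        rho, p = stats.spearmanr(me, trait)
        rows.append({"module": col, "spearman_rho": float(rho),
                     "p_value": float(p),
                     "significant": bool(p < alpha), "degenerate": False})
    return pd.DataFrame(rows)


def gene_statistics(data: pd.DataFrame, labels: pd.Series,
                    mes: pd.DataFrame, trait: np.ndarray) -> GeneStats:
    """Per-gene kME (Pearson correlation with own-module ME) and GS
    (Pearson correlation with the trait).  Unassigned genes get NaN kME."""
    trait = np.asarray(trait, dtype=float)
    rows = []
    for gene in data.index:
        prof = data.loc[gene].to_numpy(dtype=float)
        mod = int(labels.loc[gene])
        if mod != 0 and f"ME{mod}" in mes:
            kme = float(np.corrcoef(prof, mes[f"ME{mod}"])[0, 1])
        else:
            kme = np.nan
        gs = float(np.corrcoef(prof, trait)[0, 1]) if np.ptp(prof) > 0 else np.nan
        rows.append({"gene": gene, "module": mod, "kME": kme, "GS": gs})
    return GeneStats(table=pd.DataFrame(rows).set_index("gene"))


def hub_genes(stats_table: pd.DataFrame, trait_assoc: pd.DataFrame,
              kme_min: float = 0.85, gs_min: float = 0.85) -> pd.Index:
    """Hub genes: kME >= 0.85 and |GS| >= 0.85 inside trait-associated modules."""
    sig_modules = {int(m[2:]) for m in
                   trait_assoc.loc[trait_assoc["significant"], "module"]}
    t = stats_table
    mask = (t["module"].isin(sig_modules)
            & (t["kME"] >= kme_min) & (t["GS"].abs() >= gs_min))
    return t.index[mask]


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r sqrt((n-2)/(1-r^2))."""
    if not (-1.0 < r < 1.0):
        return 0.0 if abs(r) == 1.0 and n > 2 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def cross_species_module_correlation(mes_a: pd.DataFrame,
                                     mes_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every module-eigengene pair across species,
    with the t-based two-sided p at n = shared conditions."""
    if len(mes_a) != len(mes_b):
        raise ValueError("eigengene matrices must share the condition axis")
    n = len(mes_a)
    rows = []
    for ca in mes_a.columns:
        for cb in mes_b.columns:
            r = float(np.corrcoef(mes_a[ca], mes_b[cb])[0, 1])
            rows.append({"module_a": ca, "module_b": cb, "pearson_r": r,
                         "p_value": correlation_p_value(r, n)})
    return pd.DataFrame(rows)


@dataclass
class InterModularNetwork:
    edges: pd.DataFrame             # source, target, coefficient, sign
    lambdas: dict                   # target module -> chosen lambda


def intermodular_lasso(mes: pd.DataFrame, n_lambdas: int = 100) -> InterModularNetwork:
    """Directed inter-modular network by per-module lasso regression.

    Each eigengene is regressed (standardized) on all other eigengenes;
    lambda is chosen by leave-one-out CV with the one-standard-error rule;
    nonzero coefficients become signed directed edges into the response
    module.  Requires >= 3 modules and >= 3 observations.
    """
    if mes.shape[1] < 3:
        raise ValueError("need >= 3 modules for the inter-modular network")
    n = len(mes)
    if n < 3:
        raise ValueError("need >= 3 observations")
    Z = (mes - mes.mean()) / mes.std(ddof=0)
    edges = []
    lambdas = {}
    for target in mes.columns:
        y = Z[target].to_numpy()
        X = Z.drop(columns=[target]).to_numpy()
        predictors = list(Z.drop(columns=[target]).columns)
        alphas, _, _ = lasso_path(X, y, alphas=n_lambdas, max_iter=5000)
        cv_err = np.zeros((n, len(alphas)))
        for i in range(n):
            idx = np.arange(n) != i
            _, coefs, _ = lasso_path(X[idx], y[idx], alphas=alphas, max_iter=5000)
            pred = X[i] @ coefs  # n_alphas predictions
            cv_err[i] = (y[i] - pred) ** 2
        mean_err = cv_err.mean(axis=0)
        se_err = cv_err.std(axis=0, ddof=1) / np.sqrt(n)
        i_min = int(np.argmin(mean_err))
        within = np.where(mean_err <= mean_err[i_min] + se_err[i_min])[0]
        i_1se = int(within[np.argmax(alphas[within])])
        lam = float(alphas[i_1se])
        _, coefs_full, _ = lasso_path(X, y, alphas=[lam], max_iter=5000)
        beta = coefs_full[:, 0]
        lambdas[target] = lam
        for j, src in enumerate(predictors):
            if beta[j] != 0.0:
                edges.append({"source": src, "target": target,
                              "coefficient": float(beta[j]),
                              "sign": int(np.sign(beta[j]))})
    return InterModularNetwork(
        edges=pd.DataFrame(edges, columns=["source", "target", "coefficient", "sign"]),
        lambdas=lambdas)
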