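"""K-means clustering of factor-responsive DEGs by expression mode.

Genes significant for a factor are first screened by that factor's
|log2FC| threshold (1 / 0.5 / 0.25 for drought / TOD / interaction), then
clustered on z-scored mean expression profiles over the 12 stage x TOD
cells.  The number of clusters is the smallest k whose best-of-restarts
between-cluster sum of squares reaches 75% of the total; cluster pairs are
contrasted with a Welch t-test on a per-gene MD-minus-SD profile summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

FOLD_CHANGE_THRESHOLDS = {"drought": 1.0, "TOD": 0.5, "interaction": 0.25}


@dataclass
class ClusterSet:
    factor: str
    k: int
    assignments: pd.Series          # gene -> cluster label (0..k-1)
    centroids: np.ndarray
    between_ss_ratio: float
    threshold_reached: bool
    seed: int
    n_restarts: int


@dataclass
class ClusterContrast:
    cluster_a: int
    cluster_b: int
    t_statistic: float
    p_value: float
    significant: bool


def screen_by_fold_change(results: pd.DataFrame, factor: str,
                          thresholds: dict | None = None) -> pd.Index:
    """Genes significant for ``factor`` whose max |log2FC| meets that
    factor's threshold."""
    thresholds = thresholds or FOLD_CHANGE_THRESHOLDS
    if factor not in thresholds:
        raise ValueError(f"unknown factor {factor!r}")
    sub = results[(results["factor"] == factor) & results["significant"]]
    keep = sub[sub["max_abs_log2_fc"] >= thresholds[factor]]
    return pd.Index(keep["gene"])


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize gene x condition mean profiles (constant rows -> 0)."""
    m = profiles.mean(axis=1)
    s = profiles.std(axis=1, ddof=0)
    z = profiles.sub(m, axis=0).div(s.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def _ss_decomposition(X: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    within = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total, within


def cluster_degs(profiles: pd.DataFrame, k: int, seed: int = 0,
                 restarts: int = 20, factor: str = "",
                 standardize: bool = True) -> ClusterSet:
    """K-means (k-means++ seeding, best of ``restarts``) on z-scored profiles."""
    if k < 1 or k > len(profiles):
        raise ValueError("k must be in [1, n profiles]")
    Z = zscore_profiles(profiles) if standardize else profiles
    X = Z.to_numpy(dtype=float)
    if k == 1:
        labels = np.zeros(len(X), dtype=int)
        centroids = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        labels = km.labels_
        centroids = km.cluster_centers_
    total, within = _ss_decomposition(X, labels)
    ratio = 0.0 if total == 0 else 1.0 - within / total
    assert within <= total * (1 + 1e-8)
    return ClusterSet(factor=factor, k=k,
                      assignments=pd.Series(labels, index=profiles.index),
                      centroids=centroids, between_ss_ratio=float(ratio),
                      threshold_reached=True, seed=seed, n_restarts=restarts)


def select_k(profiles: pd.DataFrame, k_range=range(1, 11),
             threshold: float = 0.75, seed: int = 0,
             restarts: int = 20, standardize: bool = True) -> tuple[int, bool]:
    """Smallest k whose between-SS/total-SS ratio reaches ``threshold``.

    Returns ``(k, reached)``; when no k in the range reaches the threshold
    the largest k is returned with ``reached=False``.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to select k")
    ks = [k for k in k_range if 1 <= k <= len(profiles)]
    if not ks:
        raise ValueError("empty k range")
    for k in ks:
        cs = cluster_degs(profiles, k, seed=seed, restarts=restarts,
                          standardize=standardize)
        if cs.between_ss_ratio >= threshold:
            return k, True
    return max(ks), False


def contrast_clusters(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                      md_cols=None, sd_cols=None,
                      alpha: float = 0.05,
                      labels: tuple = (0, 1)) -> ClusterContrast:
    """Welch t-test between two clusters on the per-gene MD-minus-SD summary.

    ``md_cols``/``sd_cols`` name the moderate- and severe-drought condition
    columns; by default columns starting with "MD"/"SD" are used.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("each cluster needs >= 2 genes")

    def summary(df: pd.DataFrame) -> np.ndarray:
        md = md_cols or [c for c in df.columns if str(c).startswith("MD")]
        sd = sd_cols or [c for c in df.columns if str(c).startswith("SD")]
        if not md or not sd:
            raise ValueError("no MD/SD columns found for the contrast")
        return df[md].mean(axis=1).to_numpy() - df[sd].mean(axis=1).to_numpy()

    a, b = summary(profiles_a), summary(profiles_b)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return ClusterContrast(cluster_a=labels[0], cluster_b=labels[1],
                           t_statistic=float(t), p_value=float(p),
                           significant=bool(p <= alpha))
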