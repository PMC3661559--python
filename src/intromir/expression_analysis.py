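"""Expression analysis: k-means profile clustering, miRNA vs host-gene
Spearman correlation across matched samples, and comparison of host-gene
expression distributions between precursor categories.

miRNA read counts are normalized to scaled RPM (see
:func:`intromir.genome_io.normalize_rpm`) and log2-transformed with a
pseudocount before clustering.  Host-gene expression arrives already
normalized on a log2 scale.  Correlation pairs are dropped when the miRNA
is unexpressed (zero RPM) in three or more matched samples; |rho| > 0.5
defines the positive/negative correlation categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans


def log2_transform(rpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(rpm + pseudocount)


def kmeans_profiles(
    matrix: pd.DataFrame,
    k: int = 10,
    max_iter: int = 50,
    seed: int = 0,
) -> tuple[pd.Series, np.ndarray]:
    """Euclidean k-means (k-means++ init, fixed seed) over expression
    profiles; returns 1-based cluster labels per row and the centroids."""
    if matrix.shape[0] < k:
        raise ValueError(f"need >= {k} rows for k={k} clustering, got {matrix.shape[0]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(values)
    return pd.Series(labels + 1, index=matrix.index, name="cluster"), km.cluster_centers_


@dataclass(frozen=True)
class HostCorrelation:
    mirna_id: str
    host_gene: str
    n_samples: int
    rho: float
    category: str  # "positive" | "negative" | "none"


def _category(rho: float, threshold: float = 0.5) -> str:
    if rho > threshold:
        return "positive"
    if rho < -threshold:
        return "negative"
    return "none"


def correlate_with_host(
    mirna_rpm: pd.DataFrame,
    host_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    sample_map: dict[str, str] | None = None,
    max_zero_samples: int = 3,
    threshold: float = 0.5,
) -> list[HostCorrelation]:
    """Spearman correlation for each (miRNA, host gene) pair over matched
    samples.

    ``sample_map`` maps miRNA sample labels to host-expression sample
    labels (identity when None).  Pairs with fewer than 3 matched samples
    are skipped; miRNAs with zero RPM in ``max_zero_samples`` or more
    matched samples are dropped as unexpressed.
    """
    results = []
    for mirna_id, host_gene in pairs:
        if mirna_id not in mirna_rpm.index or host_gene not in host_expr.index:
            continue
        matched = [
            (s, (sample_map or {}).get(s, s))
            for s in mirna_rpm.columns
            if (sample_map or {}).get(s, s) in host_expr.columns
        ]
        if len(matched) < 3:
            continue
        x = mirna_rpm.loc[mirna_id, [m[0] for m in matched]].to_numpy(dtype=float)
        y = host_expr.loc[host_gene, [m[1] for m in matched]].to_numpy(dtype=float)
        if int((x == 0).sum()) >= max_zero_samples:
            continue
        rho = spearman_rho(x, y)
        results.append(
            HostCorrelation(mirna_id, host_gene, len(matched), rho,
                            _category(rho, threshold))
        )
    return results


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# --------------------------------------------------------------------------
# host-gene distribution comparison
# --------------------------------------------------------------------------

DEFAULT_BINS = np.linspace(0, 16, 9)  # 8 right-closed intervals over (0, 16]


def right_closed_histogram(values: np.ndarray, bins: np.ndarray = DEFAULT_BINS) -> np.ndarray:
    """Histogram with right-closed bins: a value exactly on an edge falls in
    the lower bin; values at or below the first edge join the first bin."""
    idx = np.digitize(values, bins[1:-1], right=True)
    return np.bincount(idx, minlength=len(bins) - 1)


def background_distribution(
    host_expr: pd.DataFrame,
    n_sample: int = 1000,
    iters: int = 1000,
    seed: int = 0,
    bins: np.ndarray = DEFAULT_BINS,
) -> np.ndarray:
    """Mean histogram of per-gene average expression over ``iters`` random
    draws of ``n_sample`` intron-containing genes."""
    rng = np.random.default_rng(seed)
    gene_means = host_expr.mean(axis=1).to_numpy(dtype=float)
    n_sample = min(n_sample, len(gene_means))
    hists = np.zeros((iters, len(bins) - 1))
    for i in range(iters):
        draw = rng.choice(gene_means, size=n_sample, replace=False)
        hists[i] = right_closed_histogram(draw, bins)
    return hists.mean(axis=0)


def rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact null distribution for
    small tie-free samples (n <= 25 each), normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 25 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def host_distribution_comparison(
    host_expr: pd.DataFrame,
    categories: dict[str, list[str]],
    n_sample: int = 1000,
    iters: int = 1000,
    seed: int = 0,
    bins: np.ndarray = DEFAULT_BINS,
) -> dict:
    """Background histogram plus per-category histograms and pairwise
    two-sided rank-sum p-values between category expression sets.

    ``categories`` maps a category name (e.g. uni/multi/cluster) to the
    host-gene ids in it; empty categories are skipped."""
    gene_means = host_expr.mean(axis=1)
    result: dict = {
        "background": background_distribution(host_expr, n_sample, iters, seed, bins),
        "bins": bins,
        "histograms": {},
        "pvalues": {},
        "category_values": {},
    }
    present = {}
    for name, genes in categories.items():
        vals = gene_means.reindex([g for g in genes if g in gene_means.index]).dropna()
        if len(vals) == 0:
            continue
        present[name] = vals.to_numpy(dtype=float)
        result["histograms"][name] = right_closed_histogram(present[name], bins)
        result["category_values"][name] = present[name]
    names = sorted(present)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            result["pvalues"][(na, nb)] = rank_sum_pvalue(present[na], present[nb])
    return result
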