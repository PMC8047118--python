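"""Expression normalization, dynamic-gene selection, trend clustering, DEGs.

The normalized expression unit is log2(RPM + 1), RPM = count / library size
x 1e6. Dynamic genes are selected as the union, over the leading principal
components, of genes in the top fraction of absolute PCA loadings, then
grouped by unsupervised hierarchical clustering of their per-stage mean
profiles into trend classes:

* Pro — continuously upregulated from TE4.5 or outgrowth onward;
* Down — continuously downregulated;
* Transient — transiently up- or downregulated.

Differential expression uses a pluggable per-gene statistic. The built-in
statistic is a Welch two-sample t test on log2(RPM + 1) replicate values
with Benjamini-Hochberg adjustment — a deliberately simple test; an
externally computed p/fold-change table (e.g. from a count-model fitter)
can be supplied instead and is filtered with identical threshold semantics:
adjusted p < p_thresh AND |log2 fold change| > lfc_thresh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .core import STAGE_INDEX, SampleMeta, stage_mean_matrix
from .enrichment import bh_adjust


def normalize_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(RPM + 1) normalization; each column's RPM sums to 1e6."""
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        bad = list(colsums.index[colsums <= 0])
        raise ValueError(f"zero library size in columns {bad}")
    rpm = counts / colsums * 1e6
    return np.log2(rpm + 1.0)


def filter_expressed(norm: pd.DataFrame, min_norm: float = 1.0) -> list[str]:
    """Genes with normalized expression strictly above ``min_norm`` in >=1 sample."""
    keep = norm.max(axis=1) > min_norm
    return list(norm.index[keep])


@dataclass
class PCAResult:
    scores: pd.DataFrame        # sample x component
    loadings: pd.DataFrame      # gene x component
    explained_variance_ratio: np.ndarray


def pca_scores_loadings(norm: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of samples in gene space: per-gene centered, unscaled.

    Sign convention: each component's loading vector is flipped so that its
    largest-magnitude entry is positive, making results reproducible across
    linear-algebra backends. If the matrix has zero variance (e.g. identical
    samples) all scores and loadings are zero.
    """
    n_samples = norm.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > n_samples:
        raise ValueError(
            f"requested {n_components} components from {n_samples} samples"
        )
    X = norm.to_numpy(dtype=float).T                    # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    total_var = float((Xc ** 2).sum())
    if total_var == 0.0:
        return PCAResult(
            pd.DataFrame(0.0, index=norm.columns, columns=comps),
            pd.DataFrame(0.0, index=norm.index, columns=comps),
            np.zeros(n_components),
        )
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    loadings = Vt[:k].T                                  # genes x k
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    evr = (S[:k] ** 2) / total_var
    if k < n_components:                                 # degenerate rank
        pad = n_components - k
        loadings = np.hstack([loadings, np.zeros((loadings.shape[0], pad))])
        scores = np.hstack([scores, np.zeros((scores.shape[0], pad))])
        evr = np.concatenate([evr, np.zeros(pad)])
    return PCAResult(
        pd.DataFrame(scores, index=norm.columns, columns=comps),
        pd.DataFrame(loadings, index=norm.index, columns=comps),
        evr,
    )


def select_top_loading_genes(
    loadings: pd.DataFrame,
    fraction: float = 0.05,
    components: Sequence[str] = ("PC1", "PC2"),
) -> list[str]:
    """Union over components of genes in the top ``fraction`` of |loading|.

    Per component, the cutoff is the ceil(n * fraction)-th largest absolute
    loading; all genes tied at the cutoff are included.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    missing = [c for c in components if c not in loadings.columns]
    if missing:
        raise ValueError(f"components {missing} not present in loadings")
    selected: set[str] = set()
    n = len(loadings)
    n_top = max(1, int(np.ceil(n * fraction)))
    for comp in components:
        absload = loadings[comp].abs()
        cutoff = absload.nlargest(n_top).iloc[-1]
        selected |= set(absload.index[absload >= cutoff])
    return sorted(selected)


@dataclass
class ClusterAssignment:
    labels: pd.Series            # gene_id -> cluster label in 1..k
    trends: dict[int, str]       # cluster -> Pro | Down | Transient
    centroids: pd.DataFrame      # cluster x stage mean profile (unscaled)

    def genes_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def genes_with_trend(self, trend: str) -> list[str]:
        clusters = {c for c, t in self.trends.items() if t == trend}
        return list(self.labels.index[self.labels.isin(clusters)])


def _trend_label(profile: np.ndarray, strict: float) -> str:
    """Classify a stage-mean centroid by the sign pattern of its differences.

    Only differences from TE4.5 onward are constrained (the earliest
    transition may go either way): Pro means no decrease beyond the
    tolerance and at least one strict increase; Down is the mirror.
    """
    diffs = np.diff(profile)
    later = diffs[1:]            # TE4.5->outgrowth, ->TSC_P1, ->TSC_Pn
    if np.all(later > -strict) and np.any(later > strict):
        return "Pro"
    if np.all(later < strict) and np.any(later < -strict):
        return "Down"
    return "Transient"


def cluster_trend_genes(
    norm: pd.DataFrame,
    samples: Sequence[SampleMeta],
    genes: Sequence[str],
    k: int = 6,
    condition: str | None = "NF",
    strict: float = 0.1,
) -> ClusterAssignment:
    """Ward hierarchical clustering of dynamic genes on z-scored stage means.

    Replicates are collapsed to stage means per condition before clustering;
    each cluster's trend class comes from its unscaled stage-mean centroid.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in norm.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    stage_means = stage_mean_matrix(norm.loc[genes], samples, condition=condition)
    X = stage_means.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    mu = X.mean(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    labels = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    # relabel clusters deterministically: by stage of centroid argmax change,
    # then by descending amplitude
    order = []
    for c in sorted(set(labels)):
        prof = X[labels == c].mean(axis=0)
        order.append((int(np.argmax(np.abs(np.diff(prof)))), -np.ptp(prof), c))
    remap = {c: i + 1 for i, (_, _, c) in enumerate(sorted(order))}
    labels = np.array([remap[c] for c in labels])
    centroids = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in sorted(set(labels))],
        index=sorted(set(labels)),
        columns=stage_means.columns,
    )
    trends = {
        int(c): _trend_label(centroids.loc[c].to_numpy(), strict)
        for c in centroids.index
    }
    return ClusterAssignment(pd.Series(labels, index=genes), trends, centroids)


def call_degs(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_thresh: float = 0.01,
    lfc_thresh: float = 2.0,
    stat_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differential expression of group A versus group B.

    Returns a table with columns lfc, p, p_adj, direction, significant.
    Direction is "up" when group A exceeds group B. ``stat_table`` (columns
    p and lfc, indexed by gene) bypasses the built-in Welch t statistic;
    the thresholds are applied identically either way.
    """
    if stat_table is not None:
        tab = stat_table.copy()
        if not {"p", "lfc"} <= set(tab.columns):
            raise ValueError("stat_table must have columns 'p' and 'lfc'")
        tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
    else:
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError(
                "built-in test needs >=2 replicates per group; supply an "
                "external stat_table for unreplicated designs"
            )
        norm = normalize_rpm(counts)
        A = norm.loc[:, list(group_a)].to_numpy(dtype=float)
        B = norm.loc[:, list(group_b)].to_numpy(dtype=float)
        lfc = A.mean(axis=1) - B.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = np.isnan(p)
        # zero within-group variance: call by mean difference alone
        p[degenerate & (lfc == 0)] = 1.0
        p[degenerate & (lfc != 0)] = 0.0
        tab = pd.DataFrame({"p": p, "lfc": lfc}, index=norm.index)
        tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
    tab["direction"] = np.where(tab["lfc"] > 0, "up", "down")
    tab.loc[tab["lfc"] == 0, "direction"] = "none"
    tab["significant"] = (tab["p_adj"] < p_thresh) & (tab["lfc"].abs() > lfc_thresh)
    return tab
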