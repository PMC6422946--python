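"""Ordination and heatmap construction.

Bray-Curtis + non-metric multidimensional scaling (NMDS) with ANOSIM for
group separation; Hellinger-transform PCA to pick the OTUs that carry
the between-sample differences; complete-linkage clustering and a
floored log10 percent-abundance matrix for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .containers import OtuTable


def hellinger(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of within-sample proportions.

    Returns a samples x OTUs matrix in which every sample row has unit
    Euclidean norm, making Euclidean-based ordination appropriate for
    compositional count data.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    mat = counts.to_numpy(dtype=float).T  # samples x OTUs
    totals = mat.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [counts.columns[i] for i in zero]
        raise ValueError(f"all-zero samples cannot be Hellinger-transformed: {names}")
    return pd.DataFrame(np.sqrt(mat / totals[:, None]),
                        index=counts.columns, columns=counts.index)


def bray_curtis(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples,
    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    counts = table.counts if isinstance(table, OtuTable) else table
    mat = counts.to_numpy(dtype=float).T
    zero = mat.sum(axis=1) == 0
    if zero.sum() >= 2:
        names = [counts.columns[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {names}")
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


# ----------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame   # samples x k
    stress: float               # Kruskal stress-1 of the best restart
    restart_stresses: list[float] = field(default_factory=list)
    anosim_R: float | None = None
    anosim_p: float | None = None


def nmds(distance_matrix: pd.DataFrame, k: int = 2, n_restarts: int = 20,
         seed: int = 0, max_iter: int = 1000, eps: float = 1e-12) -> OrdinationResult:
    """Non-metric MDS by SMACOF with monotone regression.

    Runs ``n_restarts`` random initialisations and returns the
    configuration with the lowest Kruskal stress-1; the final stress of
    every restart is kept for bookkeeping.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError(f"NMDS needs at least 3 samples, got {n}")
    best_coords, stresses = None, []
    for r in range(n_restarts):
        coords, stress = smacof(
            d, metric=False, n_components=k, n_init=1, max_iter=max_iter,
            eps=eps, random_state=seed + r, normalized_stress=True)
        stresses.append(float(stress))
        if best_coords is None or stress < min(stresses[:-1], default=np.inf):
            best_coords = coords
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(best_coords, index=distance_matrix.index, columns=cols),
        stress=min(stresses), restart_stresses=stresses)


def anosim(distance_matrix: pd.DataFrame, group_labels, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) over
    the ranks of all pairwise distances, M = n(n-1)/2.  The permutation
    p-value is (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    """
    d = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(group_labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"singleton groups not allowed: {uniq[counts < 2].tolist()}")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu])

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean())
                     / (len(ranks) / 2.0))

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)


# ----------------------------------------------------------------------

def pca_loadings(hellinger_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the (column-centered, unscaled) Hellinger matrix.

    Returns the OTU loading matrix (unit-norm right singular vectors,
    OTUs x components) and the explained variances.  Axis signs are
    arbitrary; downstream use takes absolute loadings only.
    """
    x = hellinger_matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / max(1, x.shape[0] - 1)
    loadings = pd.DataFrame(vt.T, index=hellinger_matrix.columns,
                            columns=[f"PC{i + 1}" for i in range(vt.shape[0])])
    return loadings, var


def select_discriminant_otus(table: OtuTable, k_per_axis: int,
                             axes: tuple[int, ...] = (1, 2)) -> list[str]:
    """OTUs with the largest absolute PCA loadings on the listed axes.

    The union over axes is returned (size between k and k * len(axes));
    ties in |loading| at the k-th rank are all included.
    """
    if k_per_axis < 1:
        raise ValueError("k_per_axis must be >= 1")
    if k_per_axis > table.shape[0]:
        raise ValueError(f"k_per_axis={k_per_axis} exceeds OTU count {table.shape[0]}")
    loadings, _ = pca_loadings(hellinger(table))
    selected: set[str] = set()
    for ax in axes:
        col = loadings[f"PC{ax}"].abs().sort_values(ascending=False)
        cutoff = col.iloc[k_per_axis - 1]
        selected |= set(col[col >= cutoff - 1e-12].index)
    return sorted(selected)


def cluster_samples(distance_matrix: pd.DataFrame, method: str = "complete"
                    ) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix and the dendrogram leaf order.
    """
    n = distance_matrix.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    z = hierarchy.linkage(squareform(np.asarray(distance_matrix, float), checks=False),
                          method=method)
    order = [distance_matrix.index[i] for i in hierarchy.leaves_list(z)]
    return z, order


def hellinger_distance(percent: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between Hellinger-transformed sample rows of a
    percent-abundance matrix (OTUs x samples)."""
    mat = percent.to_numpy(dtype=float).T
    totals = mat.sum(axis=1, keepdims=True)
    hel = np.sqrt(np.divide(mat, totals, out=np.zeros_like(mat), where=totals > 0))
    d = squareform(pdist(hel, metric="euclidean"))
    return pd.DataFrame(d, index=percent.columns, columns=percent.columns)


@dataclass
class HeatmapSpec:
    """Floored log10 percent-abundance matrix plus display orders."""

    matrix: pd.DataFrame          # selected OTUs x samples, log10 percent
    sample_order: list[str]
    otu_order: list[str]
    floor_pct: float
    otu_modules: dict[str, str] = field(default_factory=dict)


def heatmap_matrix(table: OtuTable, selected_otus, floor_pct: float = 0.1,
                   otu_modules: dict[str, str] | None = None) -> HeatmapSpec:
    """Log10 percent-abundance heatmap over the selected OTUs.

    Abundances are converted to percent of the sample's (within-domain)
    reads and floored at ``floor_pct`` before the log, so an absent OTU
    maps to log10(0.1) = -1 with the default floor.  Samples are ordered
    by complete-linkage clustering of Hellinger distances computed on the
    selected-OTU percent matrix; OTUs by clustering of their log
    profiles.
    """
    selected = list(selected_otus)
    if not selected:
        raise ValueError("empty OTU selection")
    missing = [o for o in selected if o not in table.otu_ids]
    if missing:
        raise ValueError(f"selected OTUs not in table: {missing}")
    pct = table.relative_abundance(per_domain=True).loc[selected] * 100.0
    logmat = np.log10(np.maximum(pct.to_numpy(), floor_pct))
    mat = pd.DataFrame(logmat, index=pct.index, columns=pct.columns)

    if pct.shape[1] >= 2:
        _, sample_order = cluster_samples(hellinger_distance(pct))
    else:
        sample_order = list(pct.columns)
    if len(selected) >= 2:
        z = hierarchy.linkage(pdist(mat.to_numpy(), metric="euclidean"), method="complete")
        otu_order = [mat.index[i] for i in hierarchy.leaves_list(z)]
    else:
        otu_order = selected
    return HeatmapSpec(matrix=mat.loc[otu_order, sample_order],
                       sample_order=sample_order, otu_order=otu_order,
                       floor_pct=floor_pct, otu_modules=dict(otu_modules or {}))
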