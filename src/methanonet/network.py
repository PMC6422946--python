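"""Co-occurrence network construction and module analysis.

Per soil: abundance-filter the rarefied OTU table (maximum within-domain
relative abundance >= 0.1 % for Bacteria, >= 1 % for Archaea), call
edges between all remaining OTUs from Spearman rank correlations of
absolute read counts (positive band 0.8 <= rho <= 0.9, Benjamini-
Hochberg q < 0.01), detect modules by multilevel (Louvain) modularity
optimisation, compute a Fruchterman-Reingold layout, and label each
module with the pre-incubation temperature at which its member OTUs are
most abundant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import CoNetwork, OtuTable

log = logging.getLogger(__name__)

#: maximum within-domain relative abundance an OTU must reach somewhere
#: to enter the network (keep-at-threshold boundary)
ABUNDANCE_THRESHOLDS = {"Bacteria": 0.001, "Archaea": 0.01}


def abundance_filter(table: OtuTable,
                     thresholds: dict[str, float] | None = None) -> OtuTable:
    """Keep OTUs whose maximum within-domain relative abundance meets the
    domain threshold (0.1 % Bacteria, 1 % Archaea by default)."""
    thr = dict(ABUNDANCE_THRESHOLDS if thresholds is None else thresholds)
    unknown = set(table.domain.unique()) - set(thr)
    if unknown:
        raise ValueError(f"no abundance threshold for domain(s) {sorted(unknown)}")
    rel = table.relative_abundance(per_domain=True)
    max_rel = rel.max(axis=1)
    cutoffs = table.domain.map(thr)
    keep = max_rel >= cutoffs
    log.info("abundance filter: %d of %d OTUs retained", int(keep.sum()), len(keep))
    return table.subset_otus(table.otu_ids[keep])


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationEdge:
    otu_a: str
    otu_b: str
    rho: float
    p: float
    q: float | None = None


def spearman_edges(table: OtuTable) -> pd.DataFrame:
    """Spearman correlations for every unordered OTU pair.

    rho is tie-corrected (Pearson on average ranks) over absolute read
    counts; p comes from the t approximation with n - 2 degrees of
    freedom.  Pairs involving a zero-variance OTU are dropped with a
    warning (rho undefined).  Returns a frame with columns otu_a, otu_b,
    rho, p.
    """
    counts = table.counts
    n_samples = counts.shape[1]
    if n_samples < 4:
        raise ValueError(f"need >= 4 samples for edge calling, got {n_samples}")
    mat = counts.to_numpy(dtype=float)
    variable = mat.std(axis=1) > 0
    dropped = counts.index[~variable].tolist()
    if dropped:
        log.warning("dropping %d zero-variance OTUs from correlation: %s",
                    len(dropped), dropped[:5])
    ids = counts.index[variable].to_list()
    sub = mat[variable.to_numpy() if hasattr(variable, "to_numpy") else variable]
    ranks = np.apply_along_axis(stats.rankdata, 1, sub)
    rho = np.corrcoef(ranks)
    # t approximation, df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n_samples - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_samples - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    iu = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({
        "otu_a": [ids[i] for i in iu[0]],
        "otu_b": [ids[j] for j in iu[1]],
        "rho": rho[iu],
        "p": p[iu],
    })


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p-value for a Spearman correlation.

    Enumerates all n! orderings of ``y``; feasible only for small n
    (the t approximation is the production path at n = 36).
    """
    import itertools

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p only supported for n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()

    def rho_of(perm):
        r = ry[list(perm)] - ry.mean()
        return float((rx_c * r).sum())

    denom = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    obs = abs(rho_of(range(n)) / denom)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(rho_of(perm) / denom) >= obs - 1e-12:
            hits += 1
    return hits / total


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q(i) = min_{j >= i} p(j) * m / j over the sorted p-values, restored
    to input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def filter_edges(edges: pd.DataFrame, rho_lo: float = 0.8, rho_hi: float = 0.9,
                 q_max: float = 0.01) -> pd.DataFrame:
    """Retain edges with rho_lo <= rho <= rho_hi (inclusive band, positive
    correlations only) and FDR-adjusted q strictly below ``q_max``."""
    if rho_lo > rho_hi:
        raise ValueError(f"rho_lo={rho_lo} > rho_hi={rho_hi}")
    out = edges.copy()
    if "q" not in out.columns:
        out["q"] = bh_fdr(out["p"].to_numpy())
    keep = (out["rho"] >= rho_lo) & (out["rho"] <= rho_hi) & (out["q"] < q_max)
    log.info("edge band filter: %d of %d pairs retained", int(keep.sum()), len(out))
    return out.loc[keep].reset_index(drop=True)


# ----------------------------------------------------------------------

def modularity(graph: nx.Graph, partition: dict[str, int], weight: str = "weight") -> float:
    """Direct evaluation of Newman-Girvan modularity,
    Q = (1/2W) * sum_ij (A_ij - k_i k_j / 2W) * delta(c_i, c_j)."""
    two_w = 2.0 * sum(d.get(weight, 1.0) for _, _, d in graph.edges(data=True))
    if two_w == 0:
        raise ValueError("modularity undefined for a graph without edge weight")
    deg = dict(graph.degree(weight=weight))
    q = 0.0
    for u, v, d in graph.edges(data=True):
        if partition[u] == partition[v]:
            q += d.get(weight, 1.0) / two_w * 2.0
    for c in set(partition.values()):
        k_c = sum(deg[n] for n in graph if partition[n] == c)
        q -= (k_c / two_w) ** 2
    return q


def louvain_modules(graph: nx.Graph, seed: int = 0, n_restarts: int = 10
                    ) -> tuple[dict[str, int], float]:
    """Multilevel (Louvain) modularity optimisation.

    Runs ``n_restarts`` seeded restarts and keeps the partition with the
    highest directly-evaluated Q.  Returns (node -> module id, Q).
    An empty graph yields an empty partition and Q = NaN.
    """
    if graph.number_of_nodes() == 0:
        return {}, float("nan")
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(graph.nodes)}, float("nan")
    best_part, best_q = None, -np.inf
    for r in range(n_restarts):
        communities = nx.community.louvain_communities(graph, weight="weight",
                                                       seed=seed + r)
        part = {n: i for i, comm in enumerate(communities) for n in comm}
        q = modularity(graph, part)
        if q > best_q:
            best_part, best_q = part, q
    return best_part, float(best_q)


def fr_layout(graph: nx.Graph, n_iter: int = 100, seed: int = 0
              ) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold force-directed layout (deterministic per seed)."""
    if graph.number_of_nodes() == 0:
        return {}
    pos = nx.spring_layout(graph, iterations=n_iter, seed=seed, weight="weight")
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


# ----------------------------------------------------------------------

def assign_module_temperature(partition: dict[str, int], table: OtuTable,
                              metadata: pd.DataFrame, temps=(25, 35, 45)
                              ) -> dict[int, str]:
    """Label each module with the pre-incubation temperature at which its
    member OTUs reach the highest mean relative abundance.

    Sample groups are defined by ``pre_temp``; ties go to the lower
    temperature with a warning; modules with zero abundance everywhere
    are labelled "unassigned".
    """
    md = metadata.set_index("sample_id")
    rel = table.relative_abundance(per_domain=True)
    rel = rel.loc[:, [c for c in rel.columns if c in md.index]]
    pre = md.loc[rel.columns, "pre_temp"].astype(int)
    labels: dict[int, str] = {}
    for module in sorted(set(partition.values())):
        members = [o for o, m in partition.items() if m == module and o in rel.index]
        if not members:
            labels[module] = "unassigned"
            continue
        means = []
        for t in temps:
            cols = pre.index[pre == int(t)]
            means.append(rel.loc[members, cols].to_numpy().mean() if len(cols) else 0.0)
        means = np.asarray(means)
        if means.max() == 0:
            labels[module] = "unassigned"
            continue
        winners = np.flatnonzero(means == means.max())
        if len(winners) > 1:
            log.warning("module %d: temperature tie %s, taking the lowest",
                        module, [temps[i] for i in winners])
        labels[module] = str(temps[int(winners[0])])
    return labels


def build_conetwork(table: OtuTable, metadata: pd.DataFrame, seed: int = 0,
                    rho_lo: float = 0.8, rho_hi: float = 0.9, q_max: float = 0.01,
                    thresholds: dict[str, float] | None = None,
                    temps=(25, 35, 45), n_restarts: int = 10,
                    layout_iter: int = 100) -> CoNetwork:
    """Full network stage for one soil's (rarefied) table."""
    filtered = abundance_filter(table, thresholds)
    edges = filter_edges(spearman_edges(filtered), rho_lo, rho_hi, q_max)
    graph = nx.Graph()
    for _, e in edges.iterrows():
        graph.add_edge(e["otu_a"], e["otu_b"], weight=float(e["rho"]),
                       p=float(e["p"]), q=float(e["q"]))
    partition, q_mod = louvain_modules(graph, seed=seed, n_restarts=n_restarts)
    layout = fr_layout(graph, n_iter=layout_iter, seed=seed)
    labels = assign_module_temperature(partition, table, metadata, temps) if partition else {}
    for node in graph.nodes:
        graph.nodes[node]["taxonomy"] = str(table.taxonomy.get(node, ""))
        graph.nodes[node]["domain"] = str(table.domain.get(node, ""))
        graph.nodes[node]["module"] = int(partition[node])
        graph.nodes[node]["temperature"] = labels.get(partition[node], "unassigned")
        graph.nodes[node]["x"], graph.nodes[node]["y"] = layout[node]
    return CoNetwork(graph=graph, modularity=q_mod, module_labels=labels)


def shared_otus(networks: dict[str, CoNetwork]) -> pd.DataFrame:
    """OTUs present in at least two soil networks, with their module
    temperature label per soil (long format: otu_id, soil, module_label)."""
    if len(networks) < 2:
        raise ValueError("need networks from at least 2 soils")
    membership: dict[str, dict[str, str]] = {}
    for soil, net in networks.items():
        for node, data in net.graph.nodes(data=True):
            membership.setdefault(node, {})[soil] = data.get("temperature", "unassigned")
    rows = [(otu, soil, label)
            for otu, per_soil in sorted(membership.items()) if len(per_soil) >= 2
            for soil, label in sorted(per_soil.items())]
    return pd.DataFrame(rows, columns=["otu_id", "soil", "module_label"])
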