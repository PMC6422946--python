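"""Rarefaction and alpha-diversity statistics.

Alpha diversity is computed on rarefied tables *including* singletons;
ordination and network stages use singleton-free tables.  All logarithms
are natural, so Shannon H' is in nats and Pielou's evenness is
H'/ln(S_obs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import OtuTable
from .letters import compact_letter_display

log = logging.getLogger(__name__)


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning (the standard `rrarefy`-style behaviour when standardising
    to the smallest library size).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.counts
    keep_cols, data = [], []
    for col in counts.columns:
        vec = counts[col].to_numpy()
        total = int(vec.sum())
        if total < depth:
            log.warning("dropping sample %s: %d reads < depth %d", col, total, depth)
            continue
        if total == depth:
            data.append(vec.copy())
        else:
            data.append(rng.multivariate_hypergeometric(vec, depth))
        keep_cols.append(col)
    out = pd.DataFrame(np.column_stack(data) if data else
                       np.empty((len(counts), 0), dtype=np.int64),
                       index=counts.index, columns=keep_cols)
    return OtuTable(out, table.taxonomy.copy())


# ----------------------------------------------------------------------

@dataclass
class DiversityRecord:
    sample_id: str
    richness: int
    shannon: float
    chao1: float
    fisher_alpha: float
    evenness: float


def _shannon(vec: np.ndarray) -> float:
    p = vec[vec > 0] / vec.sum()
    return float(-(p * np.log(p)).sum())


def _chao1(vec: np.ndarray, bias_corrected: bool = True) -> float:
    s_obs = int((vec > 0).sum())
    f1 = int((vec == 1).sum())
    f2 = int((vec == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float(s_obs + f1 * (f1 - 1) / 2.0)
    return s_obs + f1**2 / (2.0 * f2)


def fisher_alpha(s_obs: int, n_reads: int) -> float:
    """Solve S = alpha * ln(1 + N/alpha) for alpha (Fisher's log-series)."""
    if s_obs <= 0 or n_reads <= 0:
        return float("nan")
    if s_obs >= n_reads:  # log-series undefined when every read is its own taxon
        return float("inf")

    def fn(a: float) -> float:
        return a * np.log1p(n_reads / a) - s_obs

    lo, hi = 1e-10, 1e3
    while fn(hi) < 0:
        hi *= 10
        if hi > 1e14:
            return float("inf")
    return float(optimize.brentq(fn, lo, hi, xtol=1e-12, rtol=1e-14))


def alpha_diversity(table: OtuTable, bias_corrected_chao1: bool = True) -> pd.DataFrame:
    """Per-sample richness, Shannon H', Chao1, Fisher alpha and evenness.

    All-zero samples get richness 0 and NaN for the undefined indices.
    """
    rows = []
    for col in table.sample_ids:
        vec = table.counts[col].to_numpy()
        n = int(vec.sum())
        s_obs = int((vec > 0).sum())
        if n == 0:
            rows.append(DiversityRecord(col, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        h = _shannon(vec)
        j = h / np.log(s_obs) if s_obs > 1 else np.nan
        rows.append(DiversityRecord(
            col, s_obs, h, _chao1(vec, bias_corrected_chao1), fisher_alpha(s_obs, n), j))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    return out


def expected_rarefied_richness(vec: np.ndarray, depth: int) -> float:
    """Closed-form expected richness after rarefying to ``depth``:
    S - sum_i C(N - n_i, d) / C(N, d)."""
    vec = np.asarray(vec)
    vec = vec[vec > 0]
    n_tot = int(vec.sum())
    if depth > n_tot:
        raise ValueError("depth exceeds sample total")
    # hypergeometric absence probability via log-gammas for stability
    from scipy.special import gammaln

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    p_absent = np.where(
        n_tot - vec >= depth,
        np.exp(log_comb(n_tot - vec, depth) - log_comb(n_tot, depth)),
        0.0)
    return float(len(vec) - p_absent.sum())


# ----------------------------------------------------------------------

def kruskal_letter_groups(values, group_labels, alpha: float = 0.05,
                          fdr: bool = True) -> pd.DataFrame:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons folded into a
    compact letter display.

    Pairwise z statistics use the tie-corrected Dunn formulation on the
    pooled mean ranks; p-values are Benjamini-Hochberg adjusted by
    default.  Groups sharing any letter are not significantly different
    at level ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(pd.unique(labels))
    too_small = [g for g in groups if (labels == g).sum() < 2]
    if len(groups) >= 2 and too_small:
        raise ValueError(f"groups with fewer than 2 observations: {too_small}")

    means = {g: float(values[labels == g].mean()) for g in groups}
    order = sorted(groups, key=lambda g: -means[g])
    if len(groups) == 1:
        return pd.DataFrame({"group": groups, "mean": [means[groups[0]]],
                             "letters": ["a"]})

    h_stat, omnibus_p = stats.kruskal(*[values[labels == g] for g in groups])

    sig_pairs: list[tuple] = []
    pair_rows = []
    if omnibus_p < alpha:
        n = len(values)
        ranks = stats.rankdata(values)
        _, tie_counts = np.unique(values, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
        mean_rank = {g: float(ranks[labels == g].mean()) for g in groups}
        sizes = {g: int((labels == g).sum()) for g in groups}
        pvals, pairs = [], []
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                             * (1.0 / sizes[a] + 1.0 / sizes[b]))
                z = (mean_rank[a] - mean_rank[b]) / se
                pvals.append(2.0 * stats.norm.sf(abs(z)))
                pairs.append((a, b))
        pvals = np.asarray(pvals)
        adj = benjamini_hochberg(pvals) if fdr else pvals
        for (a, b), p_raw, p_adj in zip(pairs, pvals, adj):
            pair_rows.append((a, b, p_raw, p_adj))
            if p_adj < alpha:
                sig_pairs.append((a, b))

    letters = compact_letter_display(groups, sig_pairs, order=order)
    out = pd.DataFrame({"group": order,
                        "mean": [means[g] for g in order],
                        "letters": [letters[g] for g in order]})
    out.attrs["kruskal_H"] = float(h_stat)
    out.attrs["kruskal_p"] = float(omnibus_p)
    out.attrs["pairwise"] = pair_rows
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (re-exported by the network stage)."""
    from .network import bh_fdr

    return bh_fdr(p_values)
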