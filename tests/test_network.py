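import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from methanonet import network as net
from methanonet.containers import OtuTable


def _table(matrix, domains=None):
    matrix = np.atleast_2d(np.asarray(matrix))
    idx = pd.Index([f"O{i}" for i in range(matrix.shape[0])], name="otu_id")
    cols = [f"s{j}" for j in range(matrix.shape[1])]
    doms = domains or ["Bacteria"] * matrix.shape[0]
    tax = pd.Series([f"{d};f{i}" for i, d in enumerate(doms)], index=idx)
    return OtuTable(pd.DataFrame(matrix, index=idx, columns=cols), tax)


class TestAbundanceFilter:
    def test_domain_thresholds_and_boundary(self):
        # per-sample totals: bacteria 10000, archaea 1000
        bact = [[9990, 9985], [5, 5], [5, 10]]       # max 0.05 %, 0.1 %
        arch = [[990, 990], [10, 5]]                 # max exactly 1 %
        t = _table(bact + arch, ["Bacteria"] * 3 + ["Archaea"] * 2)
        kept = net.abundance_filter(t)
        assert "O1" not in kept.otu_ids              # bacterial 0.05 % removed
        assert "O2" in kept.otu_ids                  # bacterial 0.1 % kept (inclusive)
        assert "O4" in kept.otu_ids                  # archaeal 1 % kept (inclusive)

    def test_counts_survivors(self):
        rng = np.random.default_rng(0)
        above = rng.integers(500, 900, (3, 4))
        below = np.ones((2, 4), dtype=int)
        t = _table(np.vstack([above, below, [[5000, 5000, 5000, 5000]]]))
        kept = net.abundance_filter(t)
        assert kept.shape[0] == 4  # 3 above + the dominant one

    def test_unknown_domain_rejected(self):
        t = _table([[5]])
        with pytest.raises(ValueError, match="threshold"):
            net.abundance_filter(t, thresholds={"Archaea": 0.01})


def spearman_oracle(x, y):
    """Average-rank Pearson: the defining computation."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearmanEdges:
    def test_monotone_limits(self):
        t = _table([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [9, 7, 5, 3, 1]])
        edges = net.spearman_edges(t).set_index(["otu_a", "otu_b"])
        assert edges.loc[("O0", "O1"), "rho"] == pytest.approx(1.0)
        assert edges.loc[("O0", "O2"), "rho"] == pytest.approx(-1.0)

    def test_tied_example_matches_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 2, 4]
        t = _table([x, y])
        rho = net.spearman_edges(t)["rho"].iloc[0]
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_random_vectors_match_oracle(self):
        """200 random tie-rich vector pairs agree with the rank-then-
        Pearson oracle to 1e-12, and p with the scipy t approximation."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 13))
            x = rng.integers(0, 5, n)
            y = rng.integers(0, 5, n)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            edges = net.spearman_edges(_table([x, y]))
            rho = edges["rho"].iloc[0]
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)
            sp_rho, sp_p = stats.spearmanr(x, y)
            assert rho == pytest.approx(sp_rho, abs=1e-12)
            assert edges["p"].iloc[0] == pytest.approx(sp_p, abs=1e-9)

    def test_zero_variance_pairs_dropped(self):
        t = _table([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]])
        edges = net.spearman_edges(t)
        assert set(map(tuple, edges[["otu_a", "otu_b"]].to_numpy())) == {("O0", "O2")}

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            net.spearman_edges(_table([[1, 2, 3], [3, 2, 1]]))

    def test_exact_permutation_p_small_n(self):
        """The t approximation tracks the exact permutation p-value on
        small tie-free vectors: both call the same pairs significant at
        0.05 for clearly monotone data, and the exact p of a perfect
        correlation is 2/n! (two orderings reach |rho| = 1)."""
        assert net.spearman_exact_p([1, 2, 3, 4, 5], [2, 3, 5, 8, 9]) \
            == pytest.approx(2 / 120)
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.permutation(6)
            y = np.clip(x * 3 + rng.integers(-1, 2, 6), 0, None)
            p_exact = net.spearman_exact_p(x, y)
            p_t = net.spearman_edges(_table([x, y]))["p"].iloc[0]
            if p_exact < 0.01:
                assert p_t < 0.05

    def test_each_unordered_pair_once(self):
        rng = np.random.default_rng(1)
        edges = net.spearman_edges(_table(rng.integers(0, 50, (8, 6))))
        pairs = {frozenset(p) for p in edges[["otu_a", "otu_b"]].to_numpy()}
        assert len(pairs) == len(edges) == 8 * 7 // 2
        assert all(len(p) == 2 for p in pairs)


def bh_oracle(p):
    """Quadratic-time, definition-based BH step-up."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        rank = np.sum(p <= pi)
        candidates = [pj * m / np.sum(p <= pj) for pj in p if pj >= pi]
        q[i] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_single_p(self):
        assert net.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_stepup(self):
        assert net.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert net.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            net.bh_fdr([0.5, 1.5])

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert net.bh_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        p = rng.random(50)
        assert net.bh_fdr(p) == pytest.approx(
            sm.multipletests(p, method="fdr_bh")[1], abs=1e-12)


class TestFilterEdges:
    def _edges(self):
        return pd.DataFrame({
            "otu_a": ["a", "a", "b", "c"],
            "otu_b": ["b", "c", "c", "d"],
            "rho": [0.95, 0.85, 0.80, 0.86],
            "p": [1e-9, 1e-8, 1e-8, 0.5],
            "q": [0.001, 0.02, 0.005, 0.6],
        })

    def test_band_and_q(self):
        kept = net.filter_edges(self._edges())
        pairs = set(map(tuple, kept[["otu_a", "otu_b"]].to_numpy()))
        assert pairs == {("b", "c")}  # 0.95 above band; q=0.02 and q=0.6 too high

    def test_lower_bound_inclusive(self):
        kept = net.filter_edges(self._edges())
        assert 0.80 in kept["rho"].to_numpy()

    def test_bad_band(self):
        with pytest.raises(ValueError):
            net.filter_edges(self._edges(), rho_lo=0.95, rho_hi=0.9)


class TestModularity:
    def _two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0)
        return g

    def test_two_triangles_q_half(self):
        g = self._two_triangles()
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert net.modularity(g, part) == pytest.approx(0.5)

    def test_louvain_finds_triangles(self):
        part, q = net.louvain_modules(self._two_triangles(), seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(part.values())) == 2
        assert len({part[0], part[1], part[2]}) == 1

    def test_single_clique_trivial(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part, q = net.louvain_modules(g, seed=0)
        assert len(set(part.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_beats_singleton_partition(self):
        g = nx.random_partition_graph([8, 8], 0.9, 0.1, seed=2)
        nx.set_edge_attributes(g, 1.0, "weight")
        part, q = net.louvain_modules(g, seed=0)
        singletons = {n: i for i, n in enumerate(g.nodes)}
        assert q >= net.modularity(g, singletons)

    def test_planted_partition_recovery(self):
        """Louvain recovers a 3-block planted partition (20 nodes/block,
        p_in=0.9, p_out=0.02) with ARI >= 0.9 in every one of 10 seeds."""
        for seed in range(10):
            g = nx.planted_partition_graph(3, 20, 0.9, 0.02, seed=seed)
            nx.set_edge_attributes(g, 1.0, "weight")
            part, _ = net.louvain_modules(g, seed=seed)
            truth = [n // 20 for n in g.nodes]
            found = [part[n] for n in g.nodes]
            assert adjusted_rand_score(truth, found) >= 0.9

    def test_empty_graph(self):
        part, q = net.louvain_modules(nx.Graph(), seed=0)
        assert part == {} and np.isnan(q)


class TestLayout:
    def test_deterministic_and_finite(self):
        g = nx.path_graph(5)
        a = net.fr_layout(g, seed=3)
        b = net.fr_layout(g, seed=3)
        assert a == b
        assert all(np.isfinite(v).all() for v in map(np.asarray, a.values()))

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("x")
        (xy,) = net.fr_layout(g).values()
        assert np.isfinite(xy).all()

    def test_two_nodes_bounded(self):
        pos = net.fr_layout(nx.Graph([("a", "b")]), seed=0)
        d = np.linalg.norm(np.subtract(pos["a"], pos["b"]))
        assert 0 < d < 4


class TestModuleTemperature:
    def _metadata(self):
        rows = []
        for t in (25, 35, 45):
            for r in (1, 2):
                rows.append((f"I{t}_r{r}", "I", t, np.nan, r, "pre", f"I{t}"))
        return pd.DataFrame(rows, columns=[
            "sample_id", "soil", "pre_temp", "inc_temp", "replicate", "phase",
            "treatment_code"])

    def test_degenerate_support(self):
        md = self._metadata()
        counts = np.zeros((2, 6), dtype=int)
        counts[0, 4:] = 50   # only in 45-degC samples
        counts[1, :] = 10
        t = _table(counts)
        t = OtuTable(t.counts.set_axis(md.sample_id, axis=1), t.taxonomy)
        labels = net.assign_module_temperature({"O0": 0, "O1": 1}, t, md)
        assert labels[0] == "45"

    def test_argmax_by_hand(self):
        md = self._metadata()
        # O0 relative abundance by group: 25 -> 0.01, 35 -> 0.02, 45 -> 0.005
        counts = np.array([
            [10, 10, 20, 20, 5, 5],
            [990, 990, 980, 980, 995, 995]])
        t = _table(counts)
        t = OtuTable(t.counts.set_axis(md.sample_id, axis=1), t.taxonomy)
        labels = net.assign_module_temperature({"O0": 0, "O1": 1}, t, md)
        assert labels[0] == "35"

    def test_tie_goes_to_lower_temperature(self, caplog):
        md = self._metadata()
        counts = np.array([[10, 10, 10, 10, 10, 10], [90, 90, 90, 90, 90, 90]])
        t = _table(counts)
        t = OtuTable(t.counts.set_axis(md.sample_id, axis=1), t.taxonomy)
        labels = net.assign_module_temperature({"O0": 0}, t, md)
        assert labels[0] == "25"


class TestSharedOtus:
    def _network(self, members):
        g = nx.Graph()
        for otu, label in members.items():
            g.add_node(otu, temperature=label, module=0)
        from methanonet.containers import CoNetwork
        return CoNetwork(graph=g)

    def test_cross_soil_reporting(self):
        nets = {
            "I": self._network({"O1": "45", "O2": "25"}),
            "P": self._network({"O1": "45", "O3": "35"}),
            "U": self._network({"O1": "45"}),
        }
        out = net.shared_otus(nets)
        assert set(out.otu_id) == {"O1"}          # O2/O3 occur in one soil only
        assert out.module_label.tolist() == ["45", "45", "45"]

    def test_requires_two_networks(self):
        with pytest.raises(ValueError):
            net.shared_otus({"I": self._network({"O1": "45"})})


class TestEndToEnd:
    def test_default_soil_network(self, default_config, experiment):
        """Full network stage on one default synthetic soil: three major
        modules, one labelled 45 degC, planted assemblages recovered."""
        design, table, truth = experiment
        md = design[design.soil == "I"]
        sub = table.subset_samples(md.sample_id.tolist())
        cn = net.build_conetwork(sub, md, seed=default_config.seed)
        major = cn.major_modules()
        assert len(major) == 3
        assert sum(1 for m in major if cn.module_labels[m] == "45") == 1
        assem = truth.assemblage_of("I")
        part = cn.modules()
        ari = adjusted_rand_score([assem[n] for n in part], list(part.values()))
        assert ari >= 0.8
        # stored Q matches direct evaluation on the stored partition
        assert cn.modularity == pytest.approx(net.modularity(cn.graph, part))

    def test_planted_cross_soil_otu(self, experiment):
        design, table, truth = experiment
        nets = {}
        for soil in "IPU":
            md = design[design.soil == soil]
            sub = table.subset_samples(md.sample_id.tolist())
            nets[soil] = net.build_conetwork(sub, md, seed=1)
        out = net.shared_otus(nets)
        # OTU_B002 has a planted cross-soil baseline in the 25C assemblage
        assert "OTU_B002" in set(out.otu_id)
        labels = out[out.otu_id == "OTU_B002"].module_label
        assert (labels == "25").all()
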