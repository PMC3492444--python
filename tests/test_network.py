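"""Subnetwork construction and differential co-expression permutation test."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from adsig import network as net


def _edge_df(pairs):
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


class TestBuildSubnetwork:
    def test_star_graph(self):
        spokes = [f"i{k}" for k in range(5)]
        sub = net.build_subnetwork(["h"], _edge_df([("h", s) for s in spokes]),
                                   ["h"] + spokes)
        assert len(sub.nodes) == 6 and len(sub.edges) == 5
        assert sub.degree("h") == 5

    def test_seed_without_interactome_entry_is_isolated(self):
        sub = net.build_subnetwork(["lonely"], _edge_df([("a", "b")]),
                                   ["lonely", "a", "b"])
        assert "lonely" in sub.nodes and sub.degree("lonely") == 0

    def test_platform_restriction_drops_offplatform_neighbors(self):
        sub = net.build_subnetwork(["h"], _edge_df([("h", "on"), ("h", "off")]),
                                   ["h", "on"])
        assert set(sub.nodes) == {"h", "on"}

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            net.build_subnetwork(["x"], _edge_df([("a", "b")]), ["a", "b"])

    @pytest.mark.parametrize("seed", range(5))
    def test_node_set_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(60)]
        G = nx.gnp_random_graph(60, 0.08, seed=int(seed))
        G = nx.relabel_nodes(G, dict(enumerate(genes)))
        platform = set(rng.choice(genes, size=45, replace=False))
        seeds = list(rng.choice(genes, size=8, replace=False))
        expected = set()
        for s in seeds:
            if s in platform:
                expected.add(s)
            if s in G:
                expected |= {j for j in G.neighbors(s) if j in platform}
        sub = net.build_subnetwork(seeds, nx.to_pandas_edgelist(G), platform)
        assert set(sub.nodes) == expected


def _latent_pair(rng, rho, n):
    """Two vectors with Pearson correlation rho in expectation."""
    a = np.sqrt(abs(rho))
    z = rng.normal(size=n)
    x = a * z + np.sqrt(1 - a * a) * rng.normal(size=n)
    y = np.sign(rho) * a * z + np.sqrt(1 - a * a) * rng.normal(size=n)
    return x, y


class TestDiffcorrSignature:
    def _signature(self, X, groups, n_perm=200, seed=0):
        genes = list(X.index)
        edges = _edge_df([(genes[0], g) for g in genes[1:]])
        sub = net.build_subnetwork([genes[0]], edges, genes)
        return net.diffcorr_signature(sub, X, groups, "A", "B",
                                      n_perm=n_perm, seed=seed)

    def test_identical_groups_give_zero_statistic_p1(self, rng):
        half = rng.normal(size=(4, 6))
        X = pd.DataFrame(np.hstack([half, half]),
                         index=[f"g{i}" for i in range(4)],
                         columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=X.columns)
        sc = self._signature(X, groups)
        np.testing.assert_allclose(sc.genes["avg_abs_diff"], 0.0, atol=1e-12)
        assert (sc.genes["p_perm"] == 1.0).all()

    def test_opposite_perfect_correlation_attains_bound(self, rng):
        n = 8
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        X = pd.DataFrame(
            np.vstack([np.r_[z1, z2], np.r_[z1, -z2]]),
            index=["h", "i0"],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        groups = pd.Series(["A"] * n + ["B"] * n, index=X.columns)
        sc = self._signature(X, groups)
        got = sc.genes.set_index("gene_id")
        assert got.loc["h", "avg_abs_diff"] == pytest.approx(2.0)

    def test_exhaustive_3v3_matches_bruteforce_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 6)),
                         index=["h", "i0", "i1"],
                         columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=X.columns)
        sc = self._signature(X, groups, n_perm=100)  # C(6,3)=20 -> exhaustive
        got = sc.genes.set_index("gene_id")

        def avg_abs_diff(mask):
            out = {}
            for g in ("h",):
                diffs = []
                for j in ("i0", "i1"):
                    pa = np.corrcoef(X.loc[g][mask], X.loc[j][mask])[0, 1]
                    pb = np.corrcoef(X.loc[g][~mask], X.loc[j][~mask])[0, 1]
                    diffs.append(abs(pa - pb))
                out[g] = np.mean(diffs)
            return out["h"]

        obs = avg_abs_diff(np.array([True] * 3 + [False] * 3))
        null = [
            avg_abs_diff(np.isin(np.arange(6), pos))
            for pos in combinations(range(6), 3)
        ]
        expected_p = max(sum(v >= obs - 1e-12 for v in null), 1) / len(null)
        assert got.loc["h", "avg_abs_diff"] == pytest.approx(obs)
        assert got.loc["h", "p_perm"] == pytest.approx(expected_p)

    def test_group_swap_symmetry(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 14)),
                         index=["h", "i0", "i1", "i2"],
                         columns=[f"s{i}" for i in range(14)])
        groups = pd.Series(["A"] * 7 + ["B"] * 7, index=X.columns)
        genes = list(X.index)
        edges = _edge_df([(genes[0], g) for g in genes[1:]])
        sub = net.build_subnetwork([genes[0]], edges, genes)
        ab = net.diffcorr_signature(sub, X, groups, "A", "B", n_perm=150, seed=4)
        ba = net.diffcorr_signature(sub, X, groups, "B", "A", n_perm=150, seed=4)
        np.testing.assert_allclose(ab.genes["avg_abs_diff"], ba.genes["avg_abs_diff"])

    def test_constant_gene_interactor_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 12)),
                         index=["h", "i0", "flat"],
                         columns=[f"s{i}" for i in range(12)])
        X.loc["flat"] = 1.0
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=X.columns)
        sc = self._signature(X, groups)
        got = sc.genes.set_index("gene_id")
        assert got.loc["h", "n_scored"] == 1  # only i0 usable
        assert "flat" not in got.index

    def test_too_few_samples_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(2, 4)), index=["h", "i0"],
                         columns=[f"s{i}" for i in range(4)])
        groups = pd.Series(["A"] * 2 + ["B"] * 2, index=X.columns)
        with pytest.raises(ValueError, match="3 samples"):
            self._signature(X, groups)

    def test_null_type_i_error_near_nominal(self, rng):
        """One population, many genes: flagging rate at 0.05 stays binomial."""
        n_genes, n = 120, 20
        X = pd.DataFrame(rng.normal(size=(n_genes, n)),
                         index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{i}" for i in range(n)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=X.columns)
        pairs = [(f"g{2 * i}", f"g{2 * i + 1}") for i in range(n_genes // 2)]
        sub = net.build_subnetwork([a for a, _ in pairs], _edge_df(pairs), X.index)
        sc = net.diffcorr_signature(sub, X, groups, "A", "B", n_perm=200, seed=7)
        rate = sc.genes["significant"].mean()
        from scipy import stats
        hi = stats.binom.ppf(0.9995, len(sc.genes), 0.05) / len(sc.genes)
        assert rate <= hi


class TestExport:
    def test_round_trip_preserves_graph_and_attributes(self, tmp_path, rng):
        n = 10
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        X = pd.DataFrame(np.vstack([np.r_[z1, z2], np.r_[z1, -z2],
                                    rng.normal(size=2 * n)]),
                         index=["h", "i0", "i1"],
                         columns=[f"s{i}" for i in range(2 * n)])
        groups = pd.Series(["A"] * n + ["B"] * n, index=X.columns)
        edges = _edge_df([("h", "i0"), ("h", "i1")])
        sub = net.build_subnetwork(["h"], edges, X.index)
        sc = net.diffcorr_signature(sub, X, groups, "A", "B", n_perm=100, seed=1)
        paths = net.export_network(sc, sub, tmp_path, deg_genes=["h"])
        G = nx.read_graphml(paths["graphml"])
        assert set(G.nodes) == set(sub.nodes)
        assert G.number_of_edges() == len(sub.edges)
        # edge attributes equal an independent recomputation of the PCCs
        a_cols = [c for c in X.columns if groups[c] == "A"]
        b_cols = [c for c in X.columns if groups[c] == "B"]
        for u, v, d in G.edges(data=True):
            pa = np.corrcoef(X.loc[u, a_cols], X.loc[v, a_cols])[0, 1]
            pb = np.corrcoef(X.loc[u, b_cols], X.loc[v, b_cols])[0, 1]
            assert d["pcc_a"] == pytest.approx(pa)
            assert d["pcc_b"] == pytest.approx(pb)

    def test_hub_report_ranks_star_center_first(self, tmp_path, rng):
        genes = ["h"] + [f"i{k}" for k in range(5)]
        X = pd.DataFrame(rng.normal(size=(6, 12)), index=genes,
                         columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=X.columns)
        sub = net.build_subnetwork(["h"], _edge_df([("h", s) for s in genes[1:]]), genes)
        sc = net.diffcorr_signature(sub, X, groups, "A", "B", n_perm=50, seed=0)
        paths = net.export_network(sc, sub, tmp_path)
        hubs = pd.read_csv(paths["hubs"], sep="\t")
        assert hubs.iloc[0]["gene_id"] == "h" and hubs.iloc[0]["degree"] == 5
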