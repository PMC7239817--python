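import numpy as np
import pandas as pd
import pytest

from hfnet.mi_network import (
    MiNetwork,
    _bin_codes,
    apply_dpi,
    bootstrap_corr_filter,
    build_network,
    connectivity_summary,
    export_graph,
    infer_candidate_edges,
    mutual_info,
    permutation_test,
)


def bruteforce_mi(x, y, bins):
    """Independent discrete MI oracle: bin on ranks, then sum p*log(p/(pq))."""
    n = len(x)
    rx = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    ry = np.argsort(np.argsort(y, kind="stable"), kind="stable")
    bx = (rx * bins) // n
    by = (ry * bins) // n
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            pij = np.mean((bx == i) & (by == j))
            if pij > 0:
                mi += pij * np.log(pij / (np.mean(bx == i) * np.mean(by == j)))
    return mi


class TestMutualInfo:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=100)
            y = 0.5 * x + rng.normal(size=100)
            assert mutual_info(x, y) == pytest.approx(
                bruteforce_mi(x, y, 5), abs=1e-12
            )

    def test_perfect_monotone_dependence_log_b(self, rng):
        # exact equality requires the bin count to divide n (990 = 2*3^2*5*11)
        x = rng.uniform(size=990)
        for b in (3, 5, 10):
            assert mutual_info(x, x, bins=b) == pytest.approx(np.log(b), abs=1e-12)

    def test_exact_monotone_invariance(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        assert mutual_info(x, y) == mutual_info(np.exp(x), y)
        assert mutual_info(x, y) == mutual_info(x, y ** 3)
        assert mutual_info(x, y) == mutual_info(2 * x + 7, np.arctan(y))

    def test_symmetry_and_nonnegativity(self, rng):
        x, y = rng.normal(size=(2, 300))
        assert mutual_info(x, y) == pytest.approx(mutual_info(y, x), abs=1e-14)
        assert mutual_info(x, y) >= 0

    def test_independent_uniforms_small(self, rng):
        x, y = rng.uniform(size=(2, 10000))
        b = 10  # n^(1/3) clamp hits 10 at n=10000
        assert mutual_info(x, y) < (b - 1) ** 2 / (2 * 10000) * 3  # bias band

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mutual_info(np.arange(10), np.arange(10))


class TestPermutationTest:
    def test_perfect_dependence_min_p(self, rng):
        x = rng.uniform(size=200)
        mi, p = permutation_test(x, x, n_perm=199, seed=0)
        assert p == pytest.approx(1.0 / 200.0)

    def test_nonlinear_dependence_detected(self, rng):
        x = rng.uniform(size=500)
        y = np.abs(x - 0.5)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.1
        _, p = permutation_test(x, y, n_perm=499, seed=1)
        assert p < 0.01

    def test_deterministic_under_seed(self, rng):
        x, y = rng.normal(size=(2, 100))
        assert permutation_test(x, y, seed=42) == permutation_test(x, y, seed=42)

    def test_type_i_error_calibrated(self):
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            x, y = r.normal(size=(2, 60))
            _, p = permutation_test(x, y, n_perm=199, seed=rep)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_too_few_permutations(self, rng):
        x, y = rng.normal(size=(2, 50))
        with pytest.raises(ValueError):
            permutation_test(x, y, n_perm=50)


class TestCandidateEdges:
    def test_chain_edges_found(self, rng):
        n = 600
        a = rng.normal(size=n)
        b = a + 0.6 * rng.normal(size=n)
        c = b + 0.6 * rng.normal(size=n)
        data = pd.DataFrame({"A": a, "B": b, "C": c})
        edges = infer_candidate_edges(data, n_perm=199, seed=0)
        key = {frozenset((r.node_a, r.node_b)): r.candidate for r in edges.itertuples()}
        assert key[frozenset(("A", "B"))]
        assert key[frozenset(("B", "C"))]

    def test_independent_panel_few_candidates(self):
        hits = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            data = pd.DataFrame(r.normal(size=(100, 8)))
            data.columns = [f"v{j}" for j in range(8)]
            edges = infer_candidate_edges(data, n_perm=199, seed=rep)
            hits.append(edges["candidate"].mean())
        assert np.mean(hits) <= 0.05

    def test_deterministic(self, rng):
        data = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        e1 = infer_candidate_edges(data, n_perm=199, seed=3)
        e2 = infer_candidate_edges(data, n_perm=199, seed=3)
        pd.testing.assert_frame_equal(e1, e2)


def toy_edges(mis, candidates=None):
    nodes = [("A", "B"), ("A", "C"), ("B", "C")]
    df = pd.DataFrame(
        {
            "node_a": [a for a, _ in nodes],
            "node_b": [b for _, b in nodes],
            "mi": mis,
            "perm_p": [0.001] * 3,
            "bh_q": [0.001] * 3,
        }
    )
    df["candidate"] = candidates if candidates is not None else [True] * 3
    return df


class TestApplyDpi:
    def test_weakest_edge_removed_tolerance_zero(self):
        out = apply_dpi(toy_edges([0.5, 0.4, 0.1]), tolerance=0.0)
        assert list(out["dpi_removed"]) == [False, False, True]

    def test_tolerance_keeps_close_triangle(self):
        out = apply_dpi(toy_edges([0.5, 0.4, 0.38]), tolerance=0.15)
        assert not out["dpi_removed"].any()  # 0.38 >= 0.4 * 0.85

    def test_incomplete_triangle_untouched(self):
        out = apply_dpi(toy_edges([0.5, 0.4, 0.1], [True, True, False]), tolerance=0.0)
        assert not out["dpi_removed"].any()

    def test_markov_chain_indirect_edge_removed(self):
        removed = 0
        n_rep = 25
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            n = 1000
            a = r.normal(size=n)
            b = a + 0.8 * r.normal(size=n)
            c = b + 0.8 * r.normal(size=n)
            data = pd.DataFrame({"A": a, "B": b, "C": c})
            edges = infer_candidate_edges(data, n_perm=199, seed=rep)
            out = apply_dpi(edges, tolerance=0.15)
            ac = out[(out.node_a == "A") & (out.node_b == "C")]
            if not ac["candidate"].iloc[0] or ac["dpi_removed"].iloc[0]:
                removed += 1
        assert removed / n_rep >= 0.9


class TestBootstrapCorrFilter:
    def test_low_r_dropped_despite_mi(self):
        r = np.random.default_rng(0)
        n = 3000
        shared = r.normal(size=n)
        x = 0.15 * shared + np.sqrt(1 - 0.15 ** 2) * r.normal(size=n)
        y = shared
        z = r.normal(size=n)
        data = pd.DataFrame({"X": x, "Y": y, "Z": z})
        edges = infer_candidate_edges(data, n_perm=199, seed=0)
        xy = edges[(edges.node_a == "X") & (edges.node_b == "Y")]
        assert xy["candidate"].iloc[0]  # MI-significant at n=3000
        out = bootstrap_corr_filter(apply_dpi(edges), data, n_boot=200, seed=0)
        xy_out = out[(out.node_a == "X") & (out.node_b == "Y")]
        assert abs(xy_out["pearson_r"].iloc[0]) < 0.2
        assert not xy_out["retained"].iloc[0]
        assert xy_out["removal_reason"].iloc[0] == "corr_filter"

    def test_filter_chain_monotone(self, rng):
        data = pd.DataFrame(rng.normal(size=(150, 6)), columns=list("abcdef"))
        data["b"] += data["a"]
        data["c"] += data["b"]
        edges = infer_candidate_edges(data, n_perm=199, seed=1)
        out = bootstrap_corr_filter(apply_dpi(edges), data, n_boot=200, seed=1)
        assert (out["retained"] <= out["dpi_pass"]).all()
        assert (out["dpi_pass"] <= out["candidate"]).all()

    def test_null_edge_rarely_retained(self):
        retained = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            data = pd.DataFrame(r.normal(size=(100, 3)), columns=list("abc"))
            edges = infer_candidate_edges(data, n_perm=199, seed=rep)
            out = bootstrap_corr_filter(apply_dpi(edges), data, n_boot=200, seed=rep)
            retained += int(out["retained"].sum() > 0)
        assert retained <= 3


class TestConnectivityAndExport:
    def _tiny_network(self, rng, with_edges=True):
        n = 300
        f = rng.normal(size=n)
        markers = pd.DataFrame(
            {
                "marker_001": 2.0 ** (f + 0.5 * rng.normal(size=n) + 5),
                "marker_002": 2.0 ** (rng.normal(size=n) + 5),
            }
        )
        scores = pd.DataFrame(
            {
                "capacity_PC1": f + 0.4 * rng.normal(size=n),
                "capacity_PC2": rng.normal(size=n),
                "activity_PC1": f + 0.4 * rng.normal(size=n),
                "activity_PC2": rng.normal(size=n),
                "myocardial_PC1": f + 0.4 * rng.normal(size=n),
                "myocardial_PC2": rng.normal(size=n),
            }
        )
        return build_network(
            markers, scores, n_perm=199, n_boot=200, seed=0
        )

    def test_key_factor_detected(self, rng):
        net = self._tiny_network(rng)
        rep = connectivity_summary(net)
        assert "marker_001" in rep.key_factors
        assert "marker_002" not in rep.key_factors
        assert rep.per_factor.loc["marker_001", "n_categories"] == 3

    def test_empty_network_empty_report(self):
        nodes = pd.DataFrame({"type": ["marker", "marker"]}, index=["m1", "m2"])
        edges = pd.DataFrame(
            columns=[
                "node_a", "node_b", "mi", "perm_p", "bh_q", "candidate",
                "dpi_removed", "dpi_pass", "pearson_r", "r_lo", "r_hi",
                "corr_p", "corr_q", "retained", "removal_reason",
            ]
        )
        rep = connectivity_summary(MiNetwork(nodes=nodes, edges=edges))
        assert rep.key_factors == []
        assert (rep.per_factor["degree"] == 0).all()

    def test_graphml_roundtrip(self, rng, tmp_path):
        import networkx as nx

        net = self._tiny_network(rng)
        gpath = tmp_path / "net.graphml"
        tpath = tmp_path / "net.tsv"
        export_graph(net, gpath, tpath)
        g = nx.read_graphml(gpath)
        assert set(g.nodes) == set(net.nodes.index)
        assert g.number_of_edges() == int(net.edges["candidate"].sum())
        some_edge = net.edges[net.edges["candidate"]].iloc[0]
        attrs = g.edges[some_edge["node_a"], some_edge["node_b"]]
        assert attrs["mi"] == pytest.approx(some_edge["mi"])
        assert attrs["retained"] == bool(some_edge["retained"])
        tsv = pd.read_csv(tpath, sep="\t")
        assert len(tsv) == len(net.edges)

    def test_empty_graphml_valid(self, tmp_path):
        import networkx as nx

        nodes = pd.DataFrame({"type": ["marker"]}, index=["m1"])
        edges = pd.DataFrame(
            columns=[
                "node_a", "node_b", "mi", "perm_p", "bh_q", "candidate",
                "dpi_removed", "dpi_pass", "pearson_r", "r_lo", "r_hi",
                "corr_p", "corr_q", "retained", "removal_reason",
            ]
        )
        path = tmp_path / "empty.graphml"
        export_graph(MiNetwork(nodes=nodes, edges=edges), path)
        g = nx.read_graphml(path)
        assert list(g.nodes) == ["m1"]
        assert g.number_of_edges() == 0
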