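"""iGESA: Fisher p against an exact tail-sum oracle, BH against a literal
step-up reference, the member/direction loop on planted truth, and the
connectivity-map semantics."""

import math
from collections import Counter

import numpy as np
import pytest

import epiconnect as ec
from epiconnect.igesa import AnnotationTable, EnrichmentResult, storey_q
from epiconnect.matrix import ConfigError, InputError
from epiconnect.ppi import PPIReference


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact one-sided p by integer tail summation (the oracle)."""
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ) / math.comb(N, n)


def bh_step_up_reference(p: list[float]) -> list[float]:
    """Literal step-up: sort ascending, p(i)*m/i, enforce monotonicity from
    the largest rank down, cap at 1, return in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def _ann(term_sets, universe):
    return AnnotationTable.from_sets(term_sets, universe=universe)


class TestFisher:
    def test_term_equal_to_universe_gives_p_one(self):
        universe = {f"P{i}" for i in range(20)}
        ann = _ann({"T1": set(universe)}, universe)
        (res,) = ec.fisher_enrichment({"P0", "P1", "P2"}, ann)
        assert res.p_value == pytest.approx(1.0)
        assert res.k == res.n == 3

    def test_example_table_matches_tail_sum(self):
        universe = {f"P{i}" for i in range(100)}
        term = {f"P{i}" for i in range(10)}
        query = {f"P{i}" for i in range(7, 17)}  # k = 3, n = 10
        ann = _ann({"T1": term}, universe)
        (res,) = ec.fisher_enrichment(query, ann)
        assert (res.k, res.n, res.K, res.N) == (3, 10, 10, 100)
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(3, 100, 10, 10), rel=1e-12
        )

    def test_random_tables_match_tail_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(5, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k_max = min(n, K)
            k = int(rng.integers(1, k_max + 1))
            # direct check of the p-value computation used by the package
            from scipy.stats import hypergeom

            p_pkg = float(hypergeom.sf(k - 1, N, K, n))
            assert p_pkg == pytest.approx(
                hypergeom_upper_tail(k, N, K, n), rel=1e-12, abs=1e-300
            )

    def test_disjoint_query_gives_empty_result(self):
        universe = {f"P{i}" for i in range(10)}
        ann = _ann({"T1": {"P0", "P1"}}, universe)
        assert ec.fisher_enrichment({"P8", "P9"}, ann) == []

    def test_gene_ratio_and_ids(self):
        universe = {f"P{i}" for i in range(10)}
        ann = _ann({"T1": {"P0", "P1", "P2"}}, universe)
        (res,) = ec.fisher_enrichment({"P0", "P2", "P9"}, ann)
        assert res.gene_ratio == "2/3"
        assert res.bg_ratio == "3/10"
        assert res.gene_ids == ("P0", "P2")


class TestBH:
    def test_single_p_unchanged(self):
        assert ec.bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_executed_step_up(self):
        assert ec.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_order_preserved_and_capped(self):
        p = [0.9, 0.001, 0.5, 1.0]
        adj = ec.bh_adjust(p)
        assert len(adj) == 4 and adj.max() <= 1.0
        assert adj[1] == min(adj)

    def test_matches_literal_reference_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 40))).tolist()
            np.testing.assert_allclose(
                ec.bh_adjust(p), bh_step_up_reference(p), rtol=1e-12
            )

    def test_invalid_input_rejected(self):
        with pytest.raises(InputError):
            ec.bh_adjust([0.5, 1.5])

    def test_storey_q_never_exceeds_bh(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        assert (storey_q(p) <= ec.bh_adjust(p) + 1e-12).all()


class TestRunIgesa:
    def test_planted_link_attains_smallest_adjusted_p(self, study, processed_dc):
        _processed, dc = processed_dc
        truth = study["truth"]
        ref = PPIReference(
            interactions=set(study["ppi_sim"].true_edges),
            provenance={},
            filter_report=Counter(),
        )
        results = ec.run_igesa(dc, ref, study["annotations"], set(truth.members))
        member, term, direction = truth.planted_links[0]
        stratum = [
            r for r in results
            if r.chaperome_id == member and r.direction == direction
        ]
        assert stratum, "planted member produced no results"
        best = min(stratum, key=lambda r: r.p_adjust)
        assert best.term_id == term

    def test_member_without_neighbors_contributes_nothing(self, processed_dc, study):
        _processed, dc = processed_dc
        ref = PPIReference(
            interactions=set(), provenance={}, filter_report=Counter()
        )
        report = {}
        results = ec.run_igesa(
            dc, ref, study["annotations"], {"P001"}, report=report
        )
        assert results == []
        assert report["members_without_neighbors"] == 1

    def test_namespace_mismatch_is_hard_error(self, processed_dc, study):
        _processed, dc = processed_dc
        foreign_universe = {f"X{i}" for i in range(100)}
        ann = AnnotationTable.from_sets(
            {"T1": set(list(foreign_universe)[:10])}, universe=foreign_universe
        )
        ref = PPIReference(
            interactions=set(study["ppi_sim"].true_edges),
            provenance={},
            filter_report=Counter(),
        )
        with pytest.raises(InputError, match="namespace"):
            ec.run_igesa(dc, ref, ann, {"P001"})

    def test_determinism_of_result_table(self, study, processed_dc):
        _processed, dc = processed_dc
        truth = study["truth"]
        ref = PPIReference(
            interactions=set(study["ppi_sim"].true_edges),
            provenance={},
            filter_report=Counter(),
        )
        frames = [
            ec.results_to_frame(
                ec.run_igesa(dc, ref, study["annotations"], set(truth.members))
            ).to_csv()
            for _ in range(2)
        ]
        assert frames[0] == frames[1]


class TestConnectivityMap:
    def _results(self, triples_with_p):
        return [
            EnrichmentResult(
                chaperome_id=m, direction=d, term_id=t, description=t,
                k=5, n=10, K=20, N=100, p_value=p, p_adjust=p, q_value=p,
            )
            for (m, t, d), p in triples_with_p
        ]

    def test_threshold_inclusive(self):
        results = self._results(
            [(("M1", "T1", "+"), 0.0005), (("M1", "T2", "+"), 0.001),
             (("M1", "T3", "+"), 0.002)]
        )
        cmap = ec.build_connectivity_map(results, adj_p_max=0.001)
        assert cmap.n_connections == 2

    def test_vacuous_threshold_keeps_all(self):
        results = self._results(
            [(("M1", "T1", "+"), 0.5), (("M2", "T2", "-"), 0.9)]
        )
        assert ec.build_connectivity_map(results, adj_p_max=1.0).n_connections == 2

    def test_duplicate_links_counted_once(self):
        results = self._results(
            [(("M1", "T1", "+"), 0.0001), (("M1", "T1", "+"), 0.0002)]
        )
        assert ec.build_connectivity_map(results).n_connections == 1

    def test_direction_collapse_mode(self):
        results = self._results(
            [(("M1", "T1", "+"), 0.0001), (("M1", "T1", "-"), 0.0002)]
        )
        assert ec.build_connectivity_map(results).n_connections == 2
        collapsed = ec.build_connectivity_map(results, collapse_direction=True)
        assert collapsed.n_connections == 1

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            ec.build_connectivity_map([], adj_p_max=0.0)

    def test_compare_maps_set_algebra(self):
        a = ec.build_connectivity_map(
            self._results([(("M1", "T1", "+"), 1e-5), (("M1", "T2", "+"), 1e-5)]),
        )
        b = ec.build_connectivity_map(
            self._results([(("M1", "T2", "+"), 1e-5), (("M2", "T3", "-"), 1e-5)]),
        )
        cmp = ec.compare_maps(a, b)
        assert cmp["shared"] == {("M1", "T2", "+")}
        assert cmp["only_a"] == {("M1", "T1", "+")}
        assert cmp["only_b"] == {("M2", "T3", "-")}
        assert len(cmp["shared"]) + len(cmp["only_a"]) == a.n_connections

    def test_self_comparison_empty_uniques(self):
        a = ec.build_connectivity_map(self._results([(("M1", "T1", "+"), 1e-5)]))
        cmp = ec.compare_maps(a, a)
        assert cmp["only_a"] == cmp["only_b"] == set()

    def test_key_mismatch_rejected(self):
        a = ec.build_connectivity_map([], collapse_direction=True)
        b = ec.build_connectivity_map([])
        with pytest.raises(ConfigError):
            ec.compare_maps(a, b)
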