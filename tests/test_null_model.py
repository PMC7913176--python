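from collections import Counter

import numpy as np
import pytest

from netprio.centrality import CentralityTable, betweenness
from netprio.disease import extract_disease_network, seed_degree_profile
from netprio.fixtures import FixtureSpec, generate_ppin
from netprio.null_model import (
    build_strata,
    replicate_seed,
    run_null,
    sample_random_seeds,
)
from netprio.ppin_io import SeedList
from tests.conftest import net_from_edges


@pytest.fixture(scope="module")
def fixture_net():
    return generate_ppin(FixtureSpec(n_nodes=200, attachment=2, rng_seed=21))


@pytest.fixture(scope="module")
def fixture_setup(fixture_net):
    nodes = sorted(fixture_net.graph.nodes)
    seeds = SeedList(symbols=frozenset(nodes[::8]), provenance="fixture")
    disease = extract_disease_network(fixture_net, seeds)
    strata = build_strata(fixture_net)
    return seeds, disease, strata


class TestBuildStrata:
    def test_degrees_one_to_seven_width_three(self):
        import networkx as nx

        # 8-node graph whose degree multiset is {1..7} plus one filler degree 4
        g = nx.havel_hakimi_graph([7, 6, 5, 4, 4, 3, 2, 1])
        net = net_from_edges([(f"N{u}", f"N{v}") for u, v in g.edges])
        degree = dict(net.graph.degree)
        witnesses = {}  # one gene per degree 1..7
        for gene, d in sorted(degree.items()):
            witnesses.setdefault(d, gene)
        assert sorted(witnesses) == [1, 2, 3, 4, 5, 6, 7]
        strata = build_strata(net, bin_width=3)
        bins = Counter(strata.gene_bin[g] for g in witnesses.values())
        assert dict(bins) == {0: 3, 1: 3, 2: 1}
        assert strata.interval(0) == (1, 3)
        assert strata.interval(2) == (7, 9)

    def test_width_one_is_exact_degree_matching(self, fixture_net):
        strata = build_strata(fixture_net, bin_width=1)
        degree = dict(fixture_net.graph.degree)
        for b, members in strata.members.items():
            assert {degree[g] for g in members} == {b + 1}

    def test_partition_matches_independent_histogram(self):
        net = generate_ppin(FixtureSpec(n_nodes=500, rng_seed=6))
        strata = build_strata(net, bin_width=3)
        degree = dict(net.graph.degree)
        expected: dict[int, set] = {}
        for gene, d in degree.items():
            expected.setdefault((d - 1) // 3, set()).add(gene)
        assert {b: set(m) for b, m in strata.members.items()} == expected
        assert sum(len(m) for m in strata.members.values()) == net.n_nodes

    def test_every_gene_in_exactly_one_bin(self, fixture_net):
        strata = build_strata(fixture_net)
        seen = [g for m in strata.members.values() for g in m]
        assert len(seen) == len(set(seen)) == fixture_net.n_nodes

    def test_bad_width(self, fixture_net):
        with pytest.raises(ValueError):
            build_strata(fixture_net, bin_width=0)


class TestSampleRandomSeeds:
    def test_all_zero_counts_empty(self, fixture_net):
        strata = build_strata(fixture_net)
        out = sample_random_seeds(strata, {}, rng_seed=0)
        assert out.symbols == frozenset()

    def test_full_bin_selected(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        strata = build_strata(net, bin_width=3)
        want = {0: len(strata.members[0])}
        out = sample_random_seeds(strata, want, rng_seed=1)
        assert out.symbols == frozenset(strata.members[0])

    def test_deterministic(self, fixture_net):
        strata = build_strata(fixture_net)
        counts = {0: 5, 1: 2}
        a = sample_random_seeds(strata, counts, rng_seed=42)
        b = sample_random_seeds(strata, counts, rng_seed=42)
        assert a.symbols == b.symbols

    def test_over_request_error(self, fixture_net):
        strata = build_strata(fixture_net)
        with pytest.raises(ValueError, match="requested"):
            sample_random_seeds(strata, {0: 10**6}, rng_seed=0)

    def test_histogram_matches_request_exactly(self, fixture_net, fixture_setup):
        seeds, disease, strata = fixture_setup
        prof = seed_degree_profile(disease, strata)
        for rep in range(20):
            drawn = sample_random_seeds(strata, prof, replicate_seed(3, rep))
            hist = Counter(strata.gene_bin[g] for g in drawn.symbols)
            assert dict(hist) == {b: c for b, c in prof.items() if c}


class TestRunNull:
    def test_forced_true_seeds_gives_n1_r0(self, fixture_net, fixture_setup):
        seeds, disease, strata = fixture_setup
        acc = run_null(
            fixture_net, disease, strata, R=1, master_seed=0,
            _sampler=lambda rep: seeds,
        )
        for gene in disease.nodes:
            assert acc.n_g(gene) == 1
            assert acc.r_g(gene) == 0  # equality is not strictly greater

    def test_weak_tie_rule_counts_ties(self, fixture_net, fixture_setup):
        seeds, disease, strata = fixture_setup
        acc = run_null(
            fixture_net, disease, strata, R=1, master_seed=0,
            tie_rule="weak", _sampler=lambda rep: seeds,
        )
        for gene in disease.nodes:
            assert acc.r_g(gene) == 1

    def test_gene_never_seen_has_zero_counts(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        acc = run_null(fixture_net, disease, strata, R=2, master_seed=5)
        assert acc.n_g("NOT_A_GENE") == 0
        assert acc.r_g("NOT_A_GENE") == 0

    def test_matches_single_threaded_reference_loop(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        R = 50
        acc = run_null(fixture_net, disease, strata, R=R, master_seed=77)
        # independent literal re-execution of the documented loop
        prof = seed_degree_profile(disease, strata)
        baseline = betweenness(disease.network).values
        n: dict = {}
        r: dict = {}
        s: dict = {}
        for rep in range(R):
            drawn = sample_random_seeds(strata, prof, replicate_seed(77, rep))
            repnet = extract_disease_network(fixture_net, drawn)
            bc = betweenness(repnet.network)
            for gene, val in bc.values.items():
                n[gene] = n.get(gene, 0) + 1
                s[gene] = s.get(gene, 0.0) + val
                if gene in baseline and val > baseline[gene]:
                    r[gene] = r.get(gene, 0) + 1
        assert acc.n == n
        assert acc.r == r
        assert acc.bc_sum == s

    def test_invariants_and_size_summary(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        R = 30
        acc = run_null(fixture_net, disease, strata, R=R, master_seed=11)
        for gene in acc.n:
            assert 0 <= acc.r_g(gene) <= acc.n_g(gene) <= R
        assert len(acc.replicate_nodes) == R
        summary = acc.size_summary()
        assert summary["replicate_nodes_mean"] > 0

    def test_worker_invariance_bitwise(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        a = run_null(fixture_net, disease, strata, R=12, master_seed=9, workers=1)
        b = run_null(fixture_net, disease, strata, R=12, master_seed=9, workers=4)
        assert a.n == b.n and a.r == b.r
        assert a.bc_sum == b.bc_sum  # exact float equality
        assert a.replicate_nodes == b.replicate_nodes

    def test_raising_disease_bc_cannot_increase_r(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        base_bc = betweenness(disease.network)
        acc1 = run_null(
            fixture_net, disease, strata, R=25, master_seed=3, disease_bc=base_bc
        )
        boosted = CentralityTable(
            label=base_bc.label,
            values={g: v + 5.0 for g, v in base_bc.values.items()},
        )
        acc2 = run_null(
            fixture_net, disease, strata, R=25, master_seed=3, disease_bc=boosted
        )
        for gene in acc1.n:
            assert acc2.r_g(gene) <= acc1.r_g(gene)

    def test_untracked_genes_are_outside_disease_net(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        acc = run_null(fixture_net, disease, strata, R=10, master_seed=2)
        assert acc.untracked_genes().isdisjoint(disease.nodes)
        for gene in acc.untracked_genes():
            assert acc.r_g(gene) == 0

    def test_bad_args(self, fixture_net, fixture_setup):
        _, disease, strata = fixture_setup
        with pytest.raises(ValueError):
            run_null(fixture_net, disease, strata, R=0, master_seed=0)
        with pytest.raises(ValueError):
            run_null(fixture_net, disease, strata, R=1, master_seed=0, tie_rule="always")


def test_replicate_seed_is_counter_based():
    a = replicate_seed(5, 0)
    b = replicate_seed(5, 1)
    c = replicate_seed(6, 0)
    assert len({a, b, c}) == 3
    assert replicate_seed(5, 0) == a
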