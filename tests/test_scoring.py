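import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obnet.modules import FunctionalModule, build_modules
from obnet.io import GeneSetCollection
from obnet.rwr import normalize_adjacency
from obnet.scoring import (
    EnrichmentScore,
    obnet_module_score,
    permutation_pvalue,
    rank_diseases,
    running_sum_es,
)

from conftest import er_network


def brute_force_peak(order, targets, N, G):
    """Exact prefix-max oracle in rational arithmetic."""
    hit = Fraction(N - G, G)
    miss = Fraction(-G, N - G)
    total = Fraction(0)
    best = None
    for g in order:
        total += hit if g in targets else miss
        best = total if best is None or total > best else best
    return best


class TestRunningSum:
    def test_targets_first_hand_example(self):
        # N=4, G=2: +1 per hit, -1 per miss -> 1, 2, 1, 0
        assert running_sum_es(["t1", "t2", "m1", "m2"], {"t1", "t2"}, 4, 2) == 2.0

    def test_targets_last_hand_example(self):
        assert running_sum_es(["m1", "m2", "t1", "t2"], {"t1", "t2"}, 4, 2) == 0.0

    def test_degenerate_G_errors(self):
        with pytest.raises(ValueError):
            running_sum_es(["a"], set(), 4, 0)
        with pytest.raises(ValueError):
            running_sum_es(["a"], {"a"}, 4, 4)

    def test_full_traversal_endpoint_algebra(self):
        # after all N genes the sum is exactly (N - G) - G: the increments
        # are not zero-sum
        for N, G in [(10, 3), (12, 6), (7, 1)]:
            genes = [f"g{i}" for i in range(N)]
            targets = set(genes[:G])
            order = genes[::-1]
            hit, miss = (N - G) / G, -G / (N - G)
            total = sum(hit if g in targets else miss for g in order)
            assert total == pytest.approx((N - G) - G, abs=1e-9)
            # and the peak is never below the endpoint
            assert running_sum_es(order, targets, N, G) >= total - 1e-9

    @pytest.mark.parametrize("N,G", [(5, 2), (8, 3), (12, 6)])
    def test_matches_exhaustive_oracle(self, N, G):
        genes = list(range(N))
        for hit_positions in itertools.combinations(range(N), G):
            targets = set(hit_positions)
            got = running_sum_es(genes, targets, N, G)
            assert got == pytest.approx(float(brute_force_peak(genes, targets, N, G)), abs=1e-9)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_property_matches_oracle(self, data):
        N = data.draw(st.integers(3, 20))
        G = data.draw(st.integers(1, N - 1))
        order = data.draw(st.permutations(list(range(N))))
        targets = set(order[:G])  # any G genes; order is the traversal
        got = running_sum_es(order, targets, N, G)
        assert got == pytest.approx(float(brute_force_peak(order, targets, N, G)), abs=1e-9)


def module_fixture(n=60, p=0.12, seed=3):
    net = er_network(n, p, seed=seed)
    m = build_modules(net, GeneSetCollection(entries={"m": frozenset(net.nodes())}))[0]
    return m, normalize_adjacency(m.subnetwork)


class TestModuleScore:
    def test_es_beta_is_convex_combination(self):
        s = EnrichmentScore(es1=10.0, es2=0.0, beta=0.1, module_id="m", N=10, G=2)
        assert s.es_beta == pytest.approx(1.0)
        for beta in (0.25, 0.5, 0.9):
            s2 = EnrichmentScore(es1=3.0, es2=7.0, beta=beta, module_id="m", N=10, G=2)
            assert s2.es_beta == pytest.approx(beta * 3.0 + (1 - beta) * 7.0)

    def test_identical_sets_give_symmetric_scores(self):
        m, tm = module_fixture()
        genes = sorted(m.genes)[:8]
        s = obnet_module_score(m, genes, genes, tm=tm)
        assert s.es1 == pytest.approx(s.es2)

    def test_ineligible_module_errors(self):
        m, tm = module_fixture()
        with pytest.raises(ValueError, match="eligible"):
            obnet_module_score(m, sorted(m.genes)[:3], sorted(m.genes)[:8], tm=tm)

    def test_planted_proximity_beats_remote_control(self):
        # trait genes adjacent to the disease genes vs the same trait size
        # placed far away on a long path with two side communities
        import networkx as nx

        net = nx.Graph()
        for com in ("A", "B"):
            members = [f"{com}{i}" for i in range(16)]
            for i, j in itertools.combinations(range(16), 2):
                if (i * 5 + j) % 3 == 0 or j - i == 1:
                    net.add_edge(members[i], members[j])
        # bridge path between the communities
        bridge = [f"P{i}" for i in range(6)]
        net.add_edge("A0", bridge[0])
        for x, y in zip(bridge, bridge[1:]):
            net.add_edge(x, y)
        net.add_edge(bridge[-1], "B0")
        m = build_modules(net, GeneSetCollection(entries={"m": frozenset(net.nodes())}))[0]
        tm = normalize_adjacency(m.subnetwork)
        disease = [f"A{i}" for i in range(8)]
        near = [f"A{i}" for i in range(8, 14)]
        far = [f"B{i}" for i in range(8, 14)]
        s_near = obnet_module_score(m, near, disease, tm=tm)
        s_far = obnet_module_score(m, far, disease, tm=tm)
        assert s_near.es_beta > s_far.es_beta


class TestPermutationPvalue:
    def test_deterministic_given_seed(self):
        m, tm = module_fixture()
        nodes = sorted(m.genes)
        ob, dis = nodes[:7], nodes[10:18]
        a = permutation_pvalue(m, ob, dis, seed=42, tm=tm)
        b = permutation_pvalue(m, ob, dis, seed=42, tm=tm)
        assert (a.es_beta, a.z, a.p) == (b.es_beta, b.z, b.p)

    def test_normal_tail_conversion(self):
        # with p_method="normal": z -> one-sided upper-tail probability
        m, tm = module_fixture()
        nodes = sorted(m.genes)
        res = permutation_pvalue(m, nodes[:7], nodes[10:18], seed=1, tm=tm, p_method="normal")
        from scipy.stats import norm

        assert res.p == pytest.approx(float(norm.sf(res.z)), rel=1e-12)

    def test_empirical_p_bounds(self):
        m, tm = module_fixture()
        nodes = sorted(m.genes)
        res = permutation_pvalue(m, nodes[:7], nodes[10:18], n_perm=50, seed=2, tm=tm)
        assert 1 / 51 <= res.p <= 1.0

    def test_null_mean_score_has_central_p(self):
        # a trait set drawn from the same null should not be significant
        m, tm = module_fixture(seed=11)
        rng = np.random.default_rng(0)
        nodes = sorted(m.genes)
        dis = frozenset(rng.choice(nodes, 8, replace=False).tolist())
        ps = []
        for _ in range(20):
            ob = frozenset(rng.choice(sorted(set(nodes) - dis), 8, replace=False).tolist())
            ps.append(permutation_pvalue(m, ob, dis, seed=rng.integers(2**31), tm=tm).p)
        assert 0.2 < float(np.mean(ps)) < 0.8


class TestRankDiseases:
    def _result(self, disease, module, p):
        from obnet.scoring import ReachabilityResult

        return ReachabilityResult(
            trait_id="obesity", disease_id=disease, module_id=module,
            es_beta=0.0, z=0.0, p=p, n_permutations=100,
        )

    def test_bh_within_disease_and_min(self):
        results = [self._result("d1", "m1", 0.5), self._result("d1", "m2", 0.01)]
        ranking = rank_diseases(results)
        # BH on {0.5, 0.01} over 2 tests -> {0.5, 0.02}; min = 0.02
        assert ranking.loc[0, "min_adjusted_p"] == pytest.approx(0.02)
        assert ranking.loc[0, "best_module_id"] == "m2"

    def test_ordering(self):
        results = [self._result("d1", "m", 0.001), self._result("d2", "m", 0.01)]
        ranking = rank_diseases(results)
        assert list(ranking["disease_id"]) == ["d1", "d2"]

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        results = [
            self._result(f"d{i}", f"m{j}", float(rng.uniform()))
            for i in range(4)
            for j in range(5)
        ]
        rank_diseases(results)
        assert all(r.p_adjusted >= r.p - 1e-12 for r in results)

    def test_global_adjustment_option(self):
        results = [self._result("d1", "m1", 0.04), self._result("d2", "m1", 0.02)]
        rank_diseases(results, adjust="bh_global")
        assert results[0].p_adjusted == pytest.approx(0.04)
        assert results[1].p_adjusted == pytest.approx(0.04)
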