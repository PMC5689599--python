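import math

import numpy as np
import pandas as pd
import pytest

from obnet.synthetic import generate_expression
from obnet.validation import (
    ExpressionMatrix,
    count_significant_a_modules,
    mdc,
    mdc_significance,
    normal_upper_p,
    overlap_fisher,
    overlap_permutation_study,
)


def hypergeom_overlap_oracle(ov, na, nb, U):
    """Exact one-sided (enrichment) overlap p by tail summation."""
    from fractions import Fraction

    total = Fraction(0)
    for x in range(ov, min(na, nb) + 1):
        total += Fraction(math.comb(na, x) * math.comb(U - na, nb - x), math.comb(U, nb))
    return float(total)


@pytest.fixture
def modules():
    return {
        "m1": frozenset({"A", "B", "C", "D", "E"}),
        "m2": frozenset({"F", "G", "H", "I", "J"}),
    }


class TestMdc:
    def test_identical_conditions_give_one(self, modules):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((10, 6))
        genes = sorted(modules["m1"] | modules["m2"])
        values = pd.DataFrame(np.hstack([vals, vals]), index=genes,
                              columns=[f"S{i}" for i in range(12)])
        cond = pd.Series(["a"] * 6 + ["b"] * 6, index=values.columns)
        expr = ExpressionMatrix(values=values, condition=cond)
        assert mdc(expr, modules["m1"], "a", "b") == pytest.approx(1.0)

    def test_swap_inversion(self, modules):
        expr = generate_expression(modules, 30, 30, 0.7, 0.3, seed=1)
        fwd = mdc(expr, modules["m1"], "tumor", "normal")
        rev = mdc(expr, modules["m1"], "normal", "tumor")
        assert fwd == pytest.approx(1.0 / rev, rel=1e-12)

    def test_two_gene_module_equals_correlation_ratio(self):
        mods = {"m": frozenset({"A", "B"})}
        expr = generate_expression(mods, 50, 50, 0.8, 0.2, seed=2)
        ta = expr.samples_of("tumor")
        tb = expr.samples_of("normal")
        ra = abs(np.corrcoef(expr.values.loc[["A", "B"], ta])[0, 1])
        rb = abs(np.corrcoef(expr.values.loc[["A", "B"], tb])[0, 1])
        assert mdc(expr, {"A", "B"}, "tumor", "normal") == pytest.approx(ra / rb)

    def test_planted_correlation_recovers_ratio(self):
        mods = {"m": frozenset(f"A{i}" for i in range(30))}
        expr = generate_expression(mods, 200, 200, 0.8, 0.2, seed=3)
        got = mdc(expr, mods["m"], "tumor", "normal")
        assert got == pytest.approx(0.8 / 0.2, rel=0.10)

    def test_too_few_genes_errors(self, modules):
        expr = generate_expression(modules, 10, 10, 0.5, 0.5, seed=4)
        with pytest.raises(ValueError):
            mdc(expr, {"A"}, "tumor", "normal")


class TestMdcSignificance:
    def test_planted_effect_hits_empirical_floor(self, modules):
        expr = generate_expression(modules, 60, 60, 0.85, 0.1, seed=5)
        df = mdc_significance(expr, {"m1": modules["m1"]}, "tumor", "normal",
                              n_perm=200, seed=6)
        assert df.loc[0, "p"] == pytest.approx(1 / 201)

    def test_null_p_is_central(self, modules):
        # same correlation in both conditions: labels carry no information
        expr = generate_expression(modules, 40, 40, 0.5, 0.5, seed=7)
        df = mdc_significance(expr, modules, "tumor", "normal", n_perm=60, seed=8)
        assert (df["p"] > 0.05).all()

    def test_fdr_at_least_raw_p(self, modules):
        expr = generate_expression(modules, 30, 30, 0.7, 0.4, seed=9)
        df = mdc_significance(expr, modules, "tumor", "normal", n_perm=40, seed=10)
        assert (df["fdr"] >= df["p"] - 1e-12).all()


class TestOverlapFisher:
    def test_full_overlap_matches_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        half = frozenset(sorted(universe)[:10])
        tests = overlap_fisher({"a": half}, {"b": half}, universe=universe)
        assert tests[0].p == pytest.approx(hypergeom_overlap_oracle(10, 10, 10, 20), rel=1e-9)

    def test_disjoint_modules_not_enriched(self):
        universe = {f"g{i}" for i in range(10)}
        a = frozenset(sorted(universe)[:5])
        b = frozenset(sorted(universe)[5:])
        tests = overlap_fisher({"a": a}, {"b": b}, universe=universe)
        assert tests[0].p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_pairs_match_tail_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = sorted(f"g{i}" for i in range(40))
        mods_a = {f"a{j}": frozenset(rng.choice(universe, rng.integers(4, 15), replace=False).tolist()) for j in range(3)}
        mods_b = {f"b{j}": frozenset(rng.choice(universe, rng.integers(4, 15), replace=False).tolist()) for j in range(3)}
        tests = overlap_fisher(mods_a, mods_b, universe=universe)
        for t in tests:
            na, nb = len(mods_a[t.module_a]), len(mods_b[t.module_b])
            assert t.p == pytest.approx(hypergeom_overlap_oracle(t.overlap, na, nb, 40), rel=1e-9, abs=1e-12)

    def test_bh_adjustment_hand_computed(self):
        universe = sorted(f"g{i}" for i in range(12))
        # construct 4 pairs with distinct raw p, then check BH by hand
        mods_a = {"a1": frozenset(universe[:6]), "a2": frozenset(universe[6:9])}
        mods_b = {"b1": frozenset(universe[:6]), "b2": frozenset(universe[3:7])}
        tests = overlap_fisher(mods_a, mods_b, universe=universe)
        raw = sorted(t.p for t in tests)
        m = len(raw)
        expected = {}
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, raw[i] * m / (i + 1))
            expected[raw[i]] = running
        for t in tests:
            assert t.p_adjusted == pytest.approx(expected[t.p], rel=1e-9)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_fisher({"a": frozenset()}, {"b": frozenset()}, universe=set())


class TestPermutationStudy:
    def test_normal_p_formula_on_summary_statistics(self):
        z, p = normal_upper_p(6, 0.67, 1.22)
        assert z == pytest.approx(4.37, abs=0.005)
        assert 1e-6 < p < 1e-5

    def test_observed_equal_to_mean_gives_half(self):
        z, p = normal_upper_p(5.0, 5.0, 2.0)
        assert z == 0.0 and p == 0.5

    def test_size_preservation_and_null_consistency(self, rng):
        universe = sorted(f"g{i}" for i in range(60))
        mods_a = {f"a{j}": frozenset(rng.choice(universe, 10, replace=False).tolist()) for j in range(3)}
        mods_b = {f"b{j}": frozenset(rng.choice(universe, 12, replace=False).tolist()) for j in range(4)}

        def selector(mods):
            return sorted(mods)[:2]

        study = overlap_permutation_study(
            mods_a, mods_b, selector, n_perm=60, top_k=2, seed=3, universe=universe
        )
        assert study.null_counts.shape == (60,)
        assert 0 <= study.observed <= len(mods_a)
        # modules_a are random themselves: observed within 2 sd of null
        if study.sd_hits > 0:
            assert abs(study.observed - study.mean_hits) <= 2 * study.sd_hits + 1e-9


def test_count_significant_a_modules():
    from obnet.validation import OverlapTest

    tests = [
        OverlapTest("a1", "b1", 3, 0.001, 0.01),
        OverlapTest("a1", "b2", 1, 0.2, 0.4),
        OverlapTest("a2", "b1", 0, 0.9, 0.9),
    ]
    assert count_significant_a_modules(tests, alpha=0.05) == 1
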