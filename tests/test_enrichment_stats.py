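"""Permutation enrichment, BH adjustment, and the exact Fisher test."""

import math

import numpy as np
import pytest
from scipy import stats

from odontoprio.enrichment_stats import (
    bh_adjust,
    fisher_2x2,
    module_enrichment_flags,
    permutation_set_enrichment,
)

from _oracles import fisher_exact_enumeration


def _sets(n_universe, n_target, n_query, n_hit, rng=None):
    universe = {f"g{i}" for i in range(n_universe)}
    target = {f"g{i}" for i in range(n_target)}
    query = {f"g{i}" for i in range(n_hit)} | {
        f"g{i}" for i in range(n_target, n_target + n_query - n_hit)
    }
    return query, target, universe


class TestPermutationEnrichment:
    def test_query_equals_universe_has_no_freedom(self):
        uni = {f"g{i}" for i in range(50)}
        target = {f"g{i}" for i in range(10)}
        res = permutation_set_enrichment(uni, target, uni, n_perm=200, seed=1)
        assert res.observed == len(target)
        assert res.null_mean == pytest.approx(len(target))
        assert res.fold == pytest.approx(1.0)
        assert res.p_empirical == 1.0

    def test_planted_fixture_fold_and_p(self):
        # universe 1000, target 100, query 50 with 30 hits:
        # hypergeometric mean overlap = 50*100/1000 = 5, so fold ~ 6
        query, target, universe = _sets(1000, 100, 50, 30)
        res = permutation_set_enrichment(query, target, universe, n_perm=10_000, seed=2)
        assert res.observed == 30
        assert res.fold == pytest.approx(6.0, rel=0.15)
        assert res.p_empirical <= 0.001
        assert res.log2_fold == pytest.approx(math.log2(res.fold))

    def test_determinism_same_seed(self):
        query, target, universe = _sets(200, 40, 30, 12)
        a = permutation_set_enrichment(query, target, universe, n_perm=500, seed=7)
        b = permutation_set_enrichment(query, target, universe, n_perm=500, seed=7)
        assert (a.null_mean, a.p_empirical) == (b.null_mean, b.p_empirical)
        c = permutation_set_enrichment(query, target, universe, n_perm=500, seed=8)
        assert (a.null_mean, a.p_empirical) != (c.null_mean, c.p_empirical)

    def test_null_mean_matches_hypergeometric_expectation(self):
        query, target, universe = _sets(1000, 100, 50, 5)
        res = permutation_set_enrichment(query, target, universe, n_perm=10_000, seed=3)
        k, t, n = 50, 100, 1000
        expect = k * t / n
        sd = math.sqrt(k * (t / n) * (1 - t / n) * (n - k) / (n - 1))
        assert abs(res.null_mean - expect) <= 3 * sd / math.sqrt(res.n_perm)

    def test_depletion_direction(self):
        query, target, universe = _sets(500, 200, 100, 5)
        res = permutation_set_enrichment(
            query, target, universe, n_perm=2000, seed=4, direction="less"
        )
        assert res.direction == "less"
        assert res.p_empirical <= 0.01
        assert res.fold < 1

    def test_p_floor_is_one_over_nperm_plus_one(self):
        query, target, universe = _sets(1000, 50, 50, 50)
        res = permutation_set_enrichment(query, target, universe, n_perm=999, seed=5)
        assert res.p_empirical >= 1 / 1000

    def test_input_validation(self):
        uni = {"a", "b"}
        with pytest.raises(ValueError):
            permutation_set_enrichment({"z"}, set(), uni, seed=0)
        with pytest.raises(ValueError):
            permutation_set_enrichment(set(), {"z"}, uni, seed=0)
        with pytest.raises(ValueError):
            permutation_set_enrichment(set(), set(), set(), seed=0)
        with pytest.raises(ValueError):
            permutation_set_enrichment({"a"}, {"a"}, uni, n_perm=0, seed=0)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])
        assert bh_adjust([0.5]) == [0.5]

    def test_dominated_by_bonferroni(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=30).tolist()
        bh = bh_adjust(p)
        bonf = [min(1.0, x * len(p)) for x in p]
        assert all(h <= b + 1e-12 for h, b in zip(bh, bonf))

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=20)
        order = rng.permutation(20)
        direct = np.asarray(bh_adjust(p.tolist()))
        shuffled = np.asarray(bh_adjust(p[order].tolist()))
        assert np.allclose(direct[order], shuffled)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestFisher2x2:
    def test_symmetric_table(self):
        res = fisher_2x2(10, 10, 10, 10)
        assert res.odds_ratio == 1
        assert res.p_two_tailed == 1
        assert res.prop_ratio == 1

    def test_cnv_burden_table(self):
        # oligodontia among CNV carriers vs the remaining cohort
        res = fisher_2x2(3, 137, 76, 31627)
        assert float(f"{res.p_two_tailed:.2g}") == 0.0052
        assert round(res.prop_ratio, 1) == 8.9

    def test_empty_row_errors(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 5, 5)
        with pytest.raises(ValueError):
            fisher_2x2(5, 5, 0, 0)
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    def test_zero_cell_conventions(self):
        assert fisher_2x2(3, 0, 2, 5).odds_ratio == math.inf
        assert fisher_2x2(3, 2, 0, 5).prop_ratio == math.inf
        assert math.isnan(fisher_2x2(0, 3, 0, 5).prop_ratio)

    def test_matches_enumeration_oracle_small_margins(self):
        for a in range(0, 8):
            for b in range(0, 8):
                for c in range(0, 8):
                    for d in range(0, 8):
                        if a + b == 0 or c + d == 0:
                            continue
                        got = fisher_2x2(a, b, c, d).p_two_tailed
                        want = float(fisher_exact_enumeration(a, b, c, d))
                        assert abs(got - want) <= 1e-12

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b == 0 or c + d == 0:
                continue
            got = fisher_2x2(a, b, c, d).p_two_tailed
            want = stats.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)


class TestModuleFlags:
    def test_module_identical_to_degs_is_flagged(self):
        universe = {f"g{i}" for i in range(60)}
        degs = {f"g{i}" for i in range(12)}
        modules = {"m1": set(degs), "m2": {f"g{i}" for i in range(40, 52)}}
        res = module_enrichment_flags(
            modules, te_targets=set(), dental_ontology_genes=set(),
            deg_set=degs, universe=universe, n_perm=2000, seed=21,
        )
        assert res.flags["m1"].enr_degs is True
        assert res.flags["m2"].enr_degs is False

    def test_empty_category_flag_false_without_error(self):
        universe = {f"g{i}" for i in range(20)}
        res = module_enrichment_flags(
            {"m": {f"g{i}" for i in range(5)}},
            te_targets=set(), dental_ontology_genes=set(), deg_set=set(),
            universe=universe, n_perm=200, seed=1,
        )
        assert res.flags["m"].n_true() == 0

    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            module_enrichment_flags(
                {"m": {"zz"}}, set(), set(), set(),
                universe={"a"}, n_perm=10, seed=0,
            )

    def test_null_modules_rarely_flagged(self):
        # random modules vs random categories: family-wise BH at alpha=0.05
        # should flag well under 5% of module x category tests
        rng = np.random.default_rng(29)
        universe = {f"g{i}" for i in range(100)}
        uni = sorted(universe)
        n_flagged = n_tests = 0
        for rep in range(40):
            modules = {
                f"m{j}": set(rng.choice(uni, size=10, replace=False)) for j in range(3)
            }
            cats = [set(rng.choice(uni, size=25, replace=False)) for _ in range(3)]
            res = module_enrichment_flags(
                modules, te_targets=cats[0], dental_ontology_genes=cats[1],
                deg_set=cats[2], universe=universe, n_perm=500, seed=1000 + rep,
            )
            for f in res.flags.values():
                n_flagged += f.n_true()
                n_tests += 3
        assert n_flagged / n_tests <= 0.05
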