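import itertools

import numpy as np
import pytest

from msgnet.data import OccurrenceMatrix
from msgnet.nullmodels import (
    EnumerationGuardError,
    RandomisationPlan,
    checkerboard_swap,
    count_matrices,
    dyad_test,
    dyad_tests,
    enumerate_null,
    exact_p_upper,
    sample_null,
)

from conftest import make_group


def matrix(data, strata=None):
    data = np.asarray(data, dtype=np.int8)
    n, s = data.shape
    strata = strata or ["grassland"] * n
    return OccurrenceMatrix(
        data, [f"g{i}" for i in range(n)], [f"sp{j}" for j in range(s)], strata
    )


class TestCheckerboardSwap:
    def test_swaps_checkerboard(self):
        m = matrix([[1, 0], [0, 1]])
        rng = np.random.default_rng(0)
        # try until the (only possible) swap fires
        done = False
        for _ in range(100):
            if checkerboard_swap(m, rng):
                done = True
                break
        assert done
        assert m.data.tolist() == [[0, 1], [1, 0]]
        assert m.row_sums().tolist() == [1, 1] and m.col_sums().tolist() == [1, 1]

    def test_non_checkerboard_untouched(self):
        m = matrix([[1, 1], [0, 1]])
        rng = np.random.default_rng(0)
        before = m.data.copy()
        assert not any(checkerboard_swap(m, rng) for _ in range(200))
        assert (m.data == before).all()

    def test_all_ones_never_swaps(self):
        m = matrix(np.ones((4, 4)))
        rng = np.random.default_rng(1)
        assert not any(checkerboard_swap(m, rng) for _ in range(500))

    def test_stratified_preserves_stratum_sums(self):
        rng = np.random.default_rng(2)
        data = (rng.random((30, 6)) < 0.4).astype(np.int8)
        data[data.sum(axis=1) == 0, 0] = 1
        strata = ["grassland"] * 10 + ["bushland"] * 10 + ["riverine"] * 10
        m = matrix(data, strata)
        before = {h: s.copy() for h, s in m.stratum_col_sums().items()}
        for _ in range(3000):
            checkerboard_swap(m, rng, stratified=True)
        after = m.stratum_col_sums()
        for h in before:
            assert (before[h] == after[h]).all()


class TestSampleNull:
    def test_margin_conservation(self, rng):
        data = (rng.random((50, 8)) < 0.3).astype(np.int8)
        data[data.sum(axis=1) == 0, 0] = 1
        m = matrix(data)
        plan = RandomisationPlan(n_samples=200, burn_in=1000, thin=10, seed=5)
        res = sample_null(m, plan, pairs=[("sp0", "sp1")])
        assert res.samples.shape == (200, 1)
        assert res.acceptance_rate > 0

    def test_frozen_matrix_all_samples_observed(self):
        m = matrix(np.ones((3, 3)))
        plan = RandomisationPlan(n_samples=50, burn_in=100, thin=2, seed=0)
        with pytest.warns(UserWarning, match="frozen"):
            res = sample_null(m, plan, pairs=[("sp0", "sp1")])
        assert (res.samples == res.observed[0]).all()
        assert res.p_upper()[0] == 1.0

    def test_margin_forced_statistic_constant(self):
        # rows sums (2,1,1), col sums (2,2): N_ab is forced by the margins
        m = matrix([[1, 1], [1, 0], [0, 1]])
        plan = RandomisationPlan(n_samples=100, burn_in=500, thin=5, seed=1)
        res = sample_null(m, plan, pairs=[("sp0", "sp1")])
        assert np.ptp(res.samples) == 0

    def test_pvalues_never_zero(self, rng):
        data = (rng.random((20, 5)) < 0.5).astype(np.int8)
        data[data.sum(axis=1) == 0, 0] = 1
        m = matrix(data)
        plan = RandomisationPlan(n_samples=500, burn_in=1000, thin=5, seed=2)
        res = sample_null(m, plan)
        assert (res.p_upper() > 0).all()


class TestEnumeration:
    def test_forced_matrix_single_point(self):
        dist = enumerate_null(matrix([[1, 1], [1, 0], [0, 1]]), ("sp0", "sp1"))
        assert dist == {1: 1.0}

    def test_two_matrix_instance(self):
        # rows (2, 2), cols (1, 2, 1): exactly two fillings, equiprobable
        m = matrix([[1, 1, 0], [0, 1, 1]])
        assert count_matrices(m) == 2
        # both fillings put sp0 and sp1 together exactly once
        dist = enumerate_null(m, ("sp0", "sp1"))
        assert dist == {1: 1.0}
        # the two fillings are row swaps of one another, so every pairwise
        # statistic is margin-forced
        assert enumerate_null(m, ("sp0", "sp2")) == {0: 1.0}

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(5):
            data = (rng.random((4, 4)) < 0.5).astype(np.int8)
            data[data.sum(axis=1) == 0, 0] = 1
            dist = enumerate_null(matrix(data), ("sp0", "sp1"))
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_stratified_support_subset_of_unstratified(self, rng):
        data = (rng.random((5, 4)) < 0.5).astype(np.int8)
        data[data.sum(axis=1) == 0, 0] = 1
        strata = ["grassland", "grassland", "bushland", "bushland", "bushland"]
        m = matrix(data, strata)
        full = enumerate_null(m, ("sp0", "sp1"))
        strat = enumerate_null(m, ("sp0", "sp1"), stratified=True)
        assert set(strat) <= set(full)

    def test_guard_raises_on_large_space(self, rng):
        data = (rng.random((12, 12)) < 0.5).astype(np.int8)
        data[data.sum(axis=1) == 0, 0] = 1
        with pytest.raises(EnumerationGuardError):
            enumerate_null(matrix(data), ("sp0", "sp1"))


class TestChainAgainstOracle:
    @pytest.mark.parametrize("stratified", [False, True])
    @pytest.mark.parametrize("seed", [3, 11])
    def test_sampled_distribution_matches_enumeration(self, stratified, seed):
        rng = np.random.default_rng(seed)
        data = (rng.random((5, 4)) < 0.5).astype(np.int8)
        data[data.sum(axis=1) == 0, 0] = 1
        strata = ["grassland", "bushland", "grassland", "bushland", "grassland"]
        m = matrix(data, strata)
        exact = enumerate_null(m, ("sp0", "sp1"), stratified=stratified)
        plan = RandomisationPlan(
            n_samples=20_000, burn_in=2_000, thin=5, stratified=stratified, seed=seed
        )
        res = sample_null(m, plan, pairs=[("sp0", "sp1")])
        vals, counts = np.unique(res.samples[:, 0], return_counts=True)
        emp = dict(zip(vals.tolist(), (counts / counts.sum()).tolist()))
        tvd = 0.5 * sum(abs(emp.get(k, 0.0) - p) for k in set(exact) | set(emp)
                        for p in [exact.get(k, 0.0)])
        assert tvd < 0.05

    def test_serial_variant_matches_oracle(self):
        m = matrix([[1, 1, 0], [1, 0, 1], [0, 1, 0], [0, 0, 1]])
        exact = enumerate_null(m, ("sp0", "sp1"))
        plan = RandomisationPlan(n_samples=20_000, burn_in=0, thin=5, seed=4, serial=True)
        res = sample_null(m, plan, pairs=[("sp0", "sp1")])
        p_exact = exact_p_upper(exact, int(res.observed[0]))
        assert res.p_upper()[0] == pytest.approx(p_exact, abs=0.02)


class TestDyadTests:
    def _groups(self, rng, n=150):
        out = []
        for i in range(n):
            members = [s for s in ("a", "b", "c", "d") if rng.random() < 0.4] or ["a"]
            out.append(make_group(f"g{i}", members,
                                  habitat="grassland" if rng.random() < 0.5 else "bushland"))
        return out

    def test_rare_pair_skipped(self):
        groups = [make_group("g0", ["a", "b"])] + [
            make_group(f"g{i}", ["a"]) for i in range(1, 10)
        ] + [make_group(f"h{i}", ["b"]) for i in range(10)]
        plan = RandomisationPlan(n_samples=100, burn_in=200, thin=2, seed=0)
        assert dyad_test(groups, ("a", "b"), plan) is None

    def test_reports_both_null_variants(self, rng):
        groups = self._groups(rng)
        plan = RandomisationPlan(n_samples=300, burn_in=1000, thin=5, seed=0)
        results = dyad_tests(groups, plan, top=4)
        assert results
        for r in results:
            assert r.n_cooccur > 2
            assert 0 < r.p_unstratified <= 1 and 0 < r.p_stratified <= 1
        # the single-pair route agrees with the batch route
        one = dyad_test(groups, results[0].pair, plan)
        assert one.n_cooccur == results[0].n_cooccur
        assert one.dice == pytest.approx(results[0].dice)
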