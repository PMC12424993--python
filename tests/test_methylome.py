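"""Differential methylation: smoothing, DMR calling, permutation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import treeharmonize as th
from treeharmonize.methylome import (
    DmrParams,
    admissible_orderings,
    call_dmrs,
    caterpillar_cuts,
    cpg_t_statistics,
    merge_intervals,
    smooth_methylation,
)
from treeharmonize.variants import GenomicInterval


def matrix_from_fracs(fracs: pd.DataFrame, coverage: int = 30) -> th.MethylMatrix:
    tot = pd.DataFrame(coverage, index=fracs.index, columns=fracs.columns)
    mod = (fracs * coverage).round().astype(int)
    return th.MethylMatrix(list(fracs.index), list(fracs.columns), mod, tot)


def sites_index(positions, chrom="chr1"):
    return pd.MultiIndex.from_tuples(
        [(chrom, p) for p in positions], names=["chrom", "pos"]
    )


class TestSmoothing:
    def test_constant_profile_invariant(self):
        idx = sites_index(range(100, 400, 20))
        fracs = pd.DataFrame(0.8, index=idx, columns=["S1", "S2"])
        sm = smooth_methylation(matrix_from_fracs(fracs))
        assert np.allclose(sm.to_numpy(), 0.8)

    def test_isolated_site_keeps_raw_fraction(self):
        idx = sites_index([100, 50_000])
        fracs = pd.DataFrame({"S1": [0.2, 0.9]}, index=idx)
        sm = smooth_methylation(matrix_from_fracs(fracs))
        assert sm["S1"].tolist() == pytest.approx([0.2, 0.9])

    def test_step_profile_smoothed_monotone(self):
        pos = list(range(0, 4000, 40))
        idx = sites_index(pos)
        raw = [0.0 if p < 2000 else 1.0 for p in pos]
        fracs = pd.DataFrame({"S1": raw}, index=idx)
        sm = smooth_methylation(matrix_from_fracs(fracs))["S1"].to_numpy()
        assert np.all(np.diff(sm) >= -1e-12)
        assert sm.min() >= 0 and sm.max() <= 1

    def test_low_coverage_sites_excluded(self):
        idx = sites_index([100, 120, 140])
        mod = pd.DataFrame({"S1": [5, 1, 5], "S2": [5, 2, 5]}, index=idx)
        tot = pd.DataFrame({"S1": [10, 2, 10], "S2": [10, 10, 10]}, index=idx)
        m = th.MethylMatrix(list(idx), ["S1", "S2"], mod, tot)
        sm = smooth_methylation(m, DmrParams(min_cov=3))
        assert len(sm) == 2  # middle site covered by 2 reads in S1 drops


class TestTStatistics:
    def make(self, case_shift=0.0, noise=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = sites_index(range(0, n * 30, 30))
        data = {}
        for s in ("A1", "A2"):
            data[s] = 0.5 + case_shift + rng.normal(0, noise, n)
        for s in ("B1", "B2"):
            data[s] = 0.5 + rng.normal(0, noise, n)
        return pd.DataFrame(data, index=idx).clip(0, 1)

    def test_identical_groups_zero_t_central_rank(self):
        sm = self.make()
        ts = cpg_t_statistics(sm, ["A1", "A2"], ["B1", "B2"])
        assert np.allclose(ts["t"], 0.0)
        assert np.allclose(ts["rank"], 0.5, atol=0.02)

    def test_shift_with_zero_variance_uses_floor(self):
        sm = self.make(case_shift=0.3, noise=0.02, seed=1)
        ts = cpg_t_statistics(sm, ["A1", "A2"], ["B1", "B2"])
        assert (ts["t"] > 0).all()
        assert ts["diff"].mean() == pytest.approx(0.3, abs=0.03)

    def test_sign_antisymmetry(self):
        sm = self.make(case_shift=0.1, noise=0.05, seed=2)
        t1 = cpg_t_statistics(sm, ["A1", "A2"], ["B1", "B2"])["t"]
        t2 = cpg_t_statistics(sm, ["B1", "B2"], ["A1", "A2"])["t"]
        assert np.allclose(t1, -t2)

    def test_small_group_rejected(self):
        sm = self.make()
        with pytest.raises(ValueError):
            cpg_t_statistics(sm, ["A1"], ["B1", "B2"])


def tstats_frame(ranks, diffs, positions=None, chrom="chr1"):
    n = len(ranks)
    positions = positions or range(0, n * 30, 30)
    idx = sites_index(positions, chrom)
    t = np.where(np.asarray(ranks) > 0.5, 1.0, -1.0) * np.sign(diffs)
    return pd.DataFrame({"t": np.asarray(diffs) * 10, "rank": ranks,
                         "diff": diffs}, index=idx)


class TestCallDmrs:
    params = DmrParams(min_cpgs=10, min_meandiff=0.2)

    def test_qualifying_run_called(self):
        ranks = [0.99] * 10 + [0.5] * 30
        diffs = [0.3] * 10 + [0.0] * 30
        dmrs = call_dmrs(tstats_frame(ranks, diffs), self.params)
        assert len(dmrs) == 1
        assert dmrs[0].n_cpgs == 10 and dmrs[0].direction == "hyper"

    def test_nine_cpg_run_rejected(self):
        ranks = [0.99] * 9 + [0.5] * 30
        diffs = [0.3] * 9 + [0.0] * 30
        assert call_dmrs(tstats_frame(ranks, diffs), self.params) == []

    def test_small_mean_diff_rejected(self):
        ranks = [0.99] * 12 + [0.5] * 30
        diffs = [0.15] * 12 + [0.0] * 30
        assert call_dmrs(tstats_frame(ranks, diffs), self.params) == []

    def test_sign_flip_breaks_run(self):
        ranks = [0.99] * 6 + [0.01] * 6 + [0.5] * 20
        diffs = [0.3] * 6 + [-0.3] * 6 + [0.0] * 20
        assert call_dmrs(tstats_frame(ranks, diffs), self.params) == []

    def test_chromosome_change_breaks_run(self):
        ranks = [0.99] * 12
        diffs = [0.3] * 12
        idx = pd.MultiIndex.from_tuples(
            [("chr1", p) for p in range(0, 180, 30)]
            + [("chr2", p) for p in range(0, 180, 30)],
            names=["chrom", "pos"],
        )
        ts = pd.DataFrame({"t": [3.0] * 12, "rank": ranks, "diff": diffs},
                          index=idx)
        assert call_dmrs(ts, self.params) == []

    def test_case_control_swap_flips_direction(self, bundle):
        cat = bundle.truth.caterpillar_order
        rest = [s for s in bundle.tree.leaf_labels if s not in set(cat)]
        d1 = th.dmr_pipeline(bundle.methylation, cat, rest)
        d2 = th.dmr_pipeline(bundle.methylation, rest, cat)
        assert [(d.interval, d.n_cpgs) for d in d1] == [
            (d.interval, d.n_cpgs) for d in d2
        ]
        for a, b in zip(d1, d2):
            assert a.direction != b.direction
            assert a.mean_diff == pytest.approx(-b.mean_diff)

    def test_degenerate_params_report_every_extreme_cpg(self):
        ranks = np.linspace(0.001, 0.999, 200)
        diffs = np.where(ranks > 0.5, 0.3, -0.3)
        params = DmrParams(min_cpgs=1, min_meandiff=0.0)
        dmrs = call_dmrs(tstats_frame(list(ranks), list(diffs)), params)
        n_cpgs = sum(d.n_cpgs for d in dmrs)
        extreme = ((ranks < 0.025) | (ranks > 0.975)).sum()
        assert n_cpgs == extreme

    def test_planted_branch_shift_regions_recovered(self, bundle):
        cat = bundle.truth.caterpillar_order
        rest = [s for s in bundle.tree.leaf_labels if s not in set(cat)]
        dmrs = th.dmr_pipeline(bundle.methylation, cat, rest)
        shifts = [r for r in bundle.truth.meth_regions if r.kind == "branch_shift"]
        assert shifts
        for region in shifts:
            assert any(d.interval.overlaps(region.interval) for d in dmrs)


class TestDmrPermutation:
    def test_exhaustive_enumeration_count(self):
        # case size 2 over 23 sublines: all 253 assignments
        subs = [f"S{i}" for i in range(23)]
        m = th.simulate_exchangeable_methylation(subs, 8, 6, seed=0)
        p, null = th.dmr_count_permutation_test(m, 2, 0, n_perm=1000, seed=0)
        assert len(null) == 253

    def test_p_zero_when_observed_exceeds_null(self):
        # the literal fraction definition allows p = 0 at the boundary
        subs = [f"S{i}" for i in range(8)]
        m = th.simulate_exchangeable_methylation(subs, 8, 6, seed=1)
        p, null = th.dmr_count_permutation_test(m, 2, 10**6, n_perm=50, seed=1)
        assert p == 0.0

    def test_exhaustive_and_sampled_agree_when_nperm_covers(self):
        subs = [f"S{i}" for i in range(7)]  # C(7,2)=21 assignments
        m = th.simulate_exchangeable_methylation(subs, 30, 8, seed=3,
                                                 idio_rate=5)
        p1, n1 = th.dmr_count_permutation_test(m, 2, 1, n_perm=21, seed=0)
        p2, n2 = th.dmr_count_permutation_test(m, 2, 1, n_perm=1000, seed=0)
        assert sorted(n1) == sorted(n2) and p1 == p2

    def test_invalid_case_size_rejected(self):
        subs = [f"S{i}" for i in range(6)]
        m = th.simulate_exchangeable_methylation(subs, 4, 6, seed=0)
        with pytest.raises(ValueError):
            th.dmr_count_permutation_test(m, 5, 0)


class TestCaterpillarCuts:
    def test_eight_subline_clade_four_cuts(self):
        order = [f"C{i}" for i in range(8)]
        cuts = caterpillar_cuts(order)
        assert [len(case) for case, _ in cuts] == [5, 4, 3, 2]
        for case, control in cuts:
            assert case == order[-len(case):]
            assert control == order[: 8 - len(case)]

    def test_clade_of_four_single_cut(self):
        cuts = caterpillar_cuts(["a", "b", "c", "d"])
        assert len(cuts) == 1
        assert cuts[0] == (["c", "d"], ["a", "b"])

    def test_small_clade_rejected(self):
        with pytest.raises(ValueError):
            caterpillar_cuts(["a", "b", "c"])

    def test_overlapping_dmrs_merge(self):
        merged = merge_intervals([
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 50, 150),
            GenomicInterval("chr1", 300, 400),
        ])
        assert merged == [
            GenomicInterval("chr1", 0, 150),
            GenomicInterval("chr1", 300, 400),
        ]


def brute_force_tau(x, y):
    """O(n^2) concordant/discordant pair counting with tau-b correction."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sign(x[i] - x[j])
            b = np.sign(y[i] - y[j])
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a == b:
                nc += 1
            else:
                nd += 1
    denom = np.sqrt((nc + nd + tx) * (nc + nd + ty))
    return (nc - nd) / denom if denom else np.nan


class TestMannKendall:
    def test_strictly_increasing_tau_one(self):
        values = {f"s{i}": float(i) for i in range(6)}
        res = th.mann_kendall_max_tau(values, [list(values)])
        assert res.max_abs_tau == pytest.approx(1.0)

    def test_strictly_decreasing_abs_recorded(self):
        values = {f"s{i}": float(-i) for i in range(6)}
        res = th.mann_kendall_max_tau(values, [list(values)])
        assert res.max_abs_tau == pytest.approx(1.0)

    def test_sibling_swap_recovers_perfect_trend(self):
        # values (1,2,3,5,4,6,7,8): swapping positions 3-4 gives tau=1
        base = [f"s{i}" for i in range(8)]
        values = dict(zip(base, [1, 2, 3, 5, 4, 6, 7, 8]))
        orderings = admissible_orderings(base, [(3, 4)])
        res = th.mann_kendall_max_tau(values, orderings)
        assert res.max_abs_tau == pytest.approx(1.0)
        assert res.best_ordering != tuple(base)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            vals = rng.integers(0, 6, size=n).astype(float)  # with ties
            values = {f"s{i}": vals[i] for i in range(n)}
            order = [f"s{i}" for i in range(n)]
            res = th.mann_kendall_max_tau(values, [order])
            expected = brute_force_tau(np.arange(n, dtype=float), vals)
            expected = 0.0 if np.isnan(expected) else abs(expected)
            assert res.max_abs_tau == pytest.approx(expected, abs=1e-12)


class TestOrderingClasses:
    def test_eight_leaf_two_pair_count(self):
        classes = th.ordering_equivalence_classes(
            [str(i) for i in range(8)], [(1, 2), (5, 6)]
        )
        assert len(classes) == 5040
        assert all(len(c) == 8 for c in classes)

    def test_three_leaf_reversal_only(self):
        classes = th.ordering_equivalence_classes(["a", "b", "c"], [])
        assert len(classes) == 3 and all(len(c) == 2 for c in classes)

    def test_sampler_reproducible_one_per_class(self):
        classes = th.ordering_equivalence_classes(["a", "b", "c", "d"], [])
        s1 = th.sample_orderings(classes, 10, seed=5)
        s2 = th.sample_orderings(classes, 10, seed=5)
        assert s1 == s2
        member_of = {o: i for i, cls in enumerate(classes) for o in cls}
        assert len({member_of[o] for o in s1}) == len(s1)


class TestTrajectoryPermutation:
    def test_observed_zero_gives_p_one(self):
        rng = np.random.default_rng(0)
        order = [f"s{i}" for i in range(6)]
        rv = pd.DataFrame(rng.uniform(size=(5, 6)), columns=order)
        p, _ = th.trajectory_permutation_test(
            rv, {i: {f"g{i}"} for i in range(5)}, 0, order, [], n_perm=50,
            seed=0
        )
        assert p == 1.0

    def test_planted_trend_significant(self):
        # regions monotone by construction in the true order
        rng = np.random.default_rng(1)
        order = [f"s{i}" for i in range(8)]
        rows = [np.linspace(0.2, 0.8, 8) + rng.normal(0, 0.01, 8)
                for _ in range(6)]
        rv = pd.DataFrame(rows, columns=order)
        genes = {i: {f"g{i}"} for i in range(6)}
        observed = th.count_monotonic_genes(rv, genes, order, [(1, 2), (5, 6)])
        assert observed == 6
        p, _ = th.trajectory_permutation_test(
            rv, genes, observed, order, [(1, 2), (5, 6)], n_perm=500, seed=3
        )
        assert p <= 0.05

    def test_no_trend_null_large_p(self):
        order = [f"s{i}" for i in range(8)]
        big = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            rv = pd.DataFrame(rng.uniform(size=(4, 8)), columns=order)
            genes = {i: {f"g{i}"} for i in range(4)}
            observed = th.count_monotonic_genes(rv, genes, order, [(1, 2), (5, 6)])
            p, _ = th.trajectory_permutation_test(
                rv, genes, observed, order, [(1, 2), (5, 6)], n_perm=100,
                seed=rep
            )
            big += p >= 0.3
        assert big >= 15


def test_kendall_pearson_conversion():
    assert th.kendall_to_pearson(0.7) == pytest.approx(0.891, abs=0.001)
    assert round(th.kendall_to_pearson(0.7), 1) == 0.9
    assert th.kendall_to_pearson(0.0) == 0.0
    assert th.kendall_to_pearson(1.0) == pytest.approx(1.0)
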