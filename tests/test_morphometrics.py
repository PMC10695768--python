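import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msbnet import morphometrics as mo


def tiny_table(rows):
    """rows: (bouton_id, dendrite_id, position, value, alpha)."""
    df = pd.DataFrame(rows, columns=["bouton_id", "dendrite_id", "position_um",
                                     "spine_volume_um3", "contact_count"])
    df["contact_id"] = np.arange(len(df))
    df["psd_area_um2"] = df["spine_volume_um3"]
    df["az_area_um2"] = df["spine_volume_um3"]
    vol = df.groupby("bouton_id")["contact_count"].first() * 0.1
    df["bouton_volume_um3"] = df["bouton_id"].map(vol)
    return mo.validate_synapse_table(df)


class TestWithinBoutonVariances:
    def test_equal_contacts_zero_variance(self):
        t = tiny_table([(0, 0, 1.0, 3.0, 2), (0, 0, 2.0, 3.0, 2)])
        np.testing.assert_array_equal(
            mo.within_bouton_variances(t, "spine_volume_um3"), [0.0])

    def test_two_contact_unbiased_variance(self):
        a, b = 2.0, 5.0
        t = tiny_table([(0, 0, 1.0, a, 2), (0, 1, 2.0, b, 2)])
        assert mo.within_bouton_variances(t, "spine_volume_um3")[0] == \
            pytest.approx((a - b) ** 2 / 2)

    def test_alpha_range_filters(self):
        t = tiny_table([(0, 0, 1.0, 1.0, 1),
                        (1, 0, 2.0, 1.0, 2), (1, 0, 3.0, 2.0, 2)])
        assert len(mo.within_bouton_variances(t, "spine_volume_um3", (2, 5))) == 1
        with pytest.warns(UserWarning):
            out = mo.within_bouton_variances(t, "spine_volume_um3", (4, 5))
        assert len(out) == 0


class TestSSBNeighborVariances:
    def test_two_ssbs_single_group(self, rng):
        a, b = 1.0, 4.0
        t = tiny_table([(0, 0, 1.0, a, 1), (1, 0, 5.0, b, 1),
                        (2, 1, 1.0, 2.0, 2), (2, 1, 2.0, 3.0, 2)])
        v = mo.ssb_neighbor_variances(t, "spine_volume_um3", rng,
                                      matching="fixed", fixed_size=2)
        np.testing.assert_allclose(v, [(a - b) ** 2 / 2])

    def test_groups_follow_dendrite_order(self, rng):
        # positions deliberately unordered in the table
        t = tiny_table([(0, 0, 3.0, 10.0, 1), (1, 0, 1.0, 1.0, 1),
                        (2, 0, 2.0, 1.0, 1), (3, 0, 4.0, 10.0, 1),
                        (4, 1, 1.0, 2.0, 2), (4, 1, 2.0, 3.0, 2)])
        v = mo.ssb_neighbor_variances(t, "spine_volume_um3", rng,
                                      matching="fixed", fixed_size=2)
        # sorted by position: (1,1) then (10,10) -> both zero variance
        np.testing.assert_allclose(v, [0.0, 0.0])

    def test_group_size_histogram_matches_msbs(self, rng):
        from msbnet.synthetic import SynapseGenParams, generate_synapse_table
        table = generate_synapse_table(
            SynapseGenParams(n_boutons=3000, n_dendrites=5, seed=8))
        msb_alpha = (table[table.contact_count >= 2]
                     .groupby("bouton_id")["contact_count"].first().to_numpy())
        target = np.bincount(msb_alpha, minlength=6)[2:6]
        target = target / target.sum()
        _, sizes = mo.ssb_neighbor_variances(table, "spine_volume_um3", rng,
                                             return_sizes=True)
        observed = np.bincount(sizes, minlength=6)[2:6] / len(sizes)
        np.testing.assert_allclose(observed, target, atol=0.04)


class TestCliffsDelta:
    def test_known_values(self):
        assert mo.cliffs_delta([1, 2], [2, 3]) == pytest.approx(-0.75)
        assert mo.cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0
        assert mo.cliffs_delta([10, 11], [1, 2]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mo.cliffs_delta([], [1.0])

    def test_matches_brute_force_enumeration(self, rng):
        for na, nb in [(3, 7), (20, 20), (50, 50)]:
            a = rng.integers(0, 10, na).astype(float)  # ties included
            b = rng.integers(0, 10, nb).astype(float)
            brute = sum(int(x > y) - int(x < y)
                        for x in a for y in b) / (na * nb)
            assert mo.cliffs_delta(a, b) == pytest.approx(brute)

    def test_rank_path_matches_matrix_path(self, rng):
        a = rng.normal(size=3000)
        b = np.round(rng.normal(size=3000), 1)  # force ties
        diff = np.sign(a[:, None] - b[None, :]).mean()
        assert mo.cliffs_delta(a, b) == pytest.approx(float(diff), abs=1e-12)

    # values rounded to 3 decimals so the monotone transform below cannot
    # collapse distinct inputs through floating-point underflow
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100).map(lambda x: round(x, 3)),
                    min_size=1, max_size=20),
           st.lists(st.floats(-100, 100).map(lambda x: round(x, 3)),
                    min_size=1, max_size=20))
    def test_antisymmetry_and_monotone_invariance(self, a, b):
        d = mo.cliffs_delta(a, b)
        assert -1.0 <= d <= 1.0
        assert mo.cliffs_delta(b, a) == pytest.approx(-d)
        f = lambda x: np.exp(np.asarray(x) / 50.0)  # strictly increasing
        assert mo.cliffs_delta(f(a), f(b)) == pytest.approx(d)


class TestPermutationTest:
    def test_identical_groups_p_near_one(self, rng):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert mo.permutation_test(a, a.copy(), rng) > 0.9

    def test_constant_equal_groups(self, rng):
        p = mo.permutation_test([2.0, 2.0], [2.0, 2.0], rng)
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        a = np.array([1.0, 5.0, 3.0])
        b = np.array([8.0, 9.0, 4.0])
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        stats = []
        for idx in itertools.combinations(range(6), 3):
            ia = np.array(idx)
            mask = np.zeros(6, bool)
            mask[ia] = True
            stats.append(abs(pooled[mask].mean() - pooled[~mask].mean()))
        exact = np.mean([s >= obs - 1e-12 for s in stats])
        mc = mo.permutation_test(a, b, rng, n_perm=5000)
        se = np.sqrt(exact * (1 - exact) / 5000)
        assert abs(mc - exact) < 4 * se + 2 / 5001

    def test_shift_invariance_of_mean_difference(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        b = np.array([2.0, 4.0, 4.0])
        p1 = mo.permutation_test(a, b, np.random.default_rng(9))
        p2 = mo.permutation_test(a + 100.0, b + 100.0, np.random.default_rng(9))
        assert p1 == p2

    def test_default_reshuffle_count(self):
        import inspect
        assert inspect.signature(mo.permutation_test).parameters["n_perm"].default == 5000


class TestBCaBootstrap:
    def test_identical_samples_ci_contains_zero(self, rng):
        a = rng.normal(size=30)
        res = mo.bca_bootstrap_diff(a, a.copy(), rng, n_boot=2000)
        assert res.low <= 0.0 <= res.high

    def test_symmetric_case_reduces_to_percentile(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 200)
        res = mo.bca_bootstrap_diff(a, b, rng, stat="mean_difference",
                                    n_boot=4000)
        from scipy import stats as sps
        oracle = sps.bootstrap((a, b), lambda x, y, axis: np.mean(x, axis=axis)
                               - np.mean(y, axis=axis),
                               method="percentile", n_resamples=4000,
                               random_state=np.random.default_rng(4))
        width = res.high - res.low
        assert res.low == pytest.approx(oracle.confidence_interval.low,
                                        abs=0.15 * width)
        assert res.high == pytest.approx(oracle.confidence_interval.high,
                                         abs=0.15 * width)

    def test_agrees_with_scipy_bca_on_skewed_data(self, rng):
        a = rng.lognormal(0, 1, 80)
        b = rng.lognormal(0.5, 1, 80)
        res = mo.bca_bootstrap_diff(a, b, rng, stat="mean_difference",
                                    n_boot=4000)
        from scipy import stats as sps
        oracle = sps.bootstrap((a, b), lambda x, y, axis: np.mean(x, axis=axis)
                               - np.mean(y, axis=axis),
                               method="BCa", n_resamples=4000,
                               random_state=np.random.default_rng(8))
        width = res.high - res.low
        assert res.method == "bca"
        assert res.low == pytest.approx(oracle.confidence_interval.low,
                                        abs=0.2 * width)
        assert res.high == pytest.approx(oracle.confidence_interval.high,
                                         abs=0.2 * width)

    def test_degenerate_falls_back_to_percentile(self, rng):
        a = np.full(5, 2.0)
        b = np.full(5, 1.0)
        with pytest.warns(UserWarning):
            res = mo.bca_bootstrap_diff(a, b, rng, n_boot=200)
        assert res.method == "percentile"
        assert res.estimate == pytest.approx(1.0)

    def test_default_bootstrap_count(self):
        import inspect
        assert inspect.signature(mo.bca_bootstrap_diff).parameters["n_boot"].default == 5000


class TestRyanHolm:
    def test_levels(self):
        np.testing.assert_allclose(mo.ryan_holm_adjust(1), [0.95])
        levels4 = mo.ryan_holm_adjust(4)
        assert levels4[0] == pytest.approx(1 - 0.05 / 4)
        assert levels4[-1] == pytest.approx(0.95)
        assert mo.ryan_holm_adjust(12)[0] == pytest.approx(1 - 0.05 / 12)
        assert (np.diff(levels4) < 0).all()  # step-down: rank 1 strictest

    def test_holm_pvalues_match_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 0.2, size=12)
        mine = mo.holm_adjust_pvalues(p)
        _, theirs, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(mine, theirs)


class TestVarianceComparisonPipeline:
    def test_detects_within_bouton_similarity(self, synth_table):
        rng = np.random.default_rng(0)
        res = mo.compare_msb_ssb_variances(synth_table, "psd_area_um2", rng,
                                           n_perm=2000, n_boot=2000)
        assert res.cliffs_delta < 0
        assert res.mean_difference < 0
        assert res.bootstrap.high < 0  # CI separated from zero

    def test_requires_both_groups(self, rng):
        t = tiny_table([(0, 0, 1.0, 1.0, 1), (1, 0, 2.0, 2.0, 1)])
        with pytest.raises(ValueError):
            mo.compare_msb_ssb_variances(t, "spine_volume_um3", rng)


class TestNeuriteTree:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):  # two roots
            mo.NeuriteTree(xyz=np.zeros((2, 3)), parent=np.array([-1, -1]))
        with pytest.raises(ValueError):  # parent after child
            mo.NeuriteTree(xyz=np.zeros((3, 3)), parent=np.array([-1, 2, 0]))

    def test_path_distances_monotone(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]], float)
        tree = mo.NeuriteTree(xyz=xyz, parent=np.array([-1, 0, 1, 1]))
        d = tree.path_distances()
        assert (d[1:] >= d[tree.parent[1:]]).all()
        np.testing.assert_allclose(d, [0, 1, 2, 2])

    def test_swc_roundtrip_exact(self, tmp_path, rng):
        from msbnet.synthetic import TreeGenParams, generate_neurite_tree
        tree = generate_neurite_tree(TreeGenParams(seed=2,
                                                   total_extent_um=40.0))
        path = tmp_path / "cell.swc"
        mo.write_swc(tree, path)
        back = mo.read_swc(path)
        np.testing.assert_array_equal(back.xyz, tree.xyz)
        np.testing.assert_array_equal(back.parent, tree.parent)

    def test_read_swc_arbitrary_ids(self, tmp_path):
        text = ("# comment\n"
                "10 1 0.0 0.0 0.0 1.0 -1\n"
                "20 3 1.0 0.0 0.0 0.5 10\n"
                "30 3 2.0 0.0 0.0 0.5 20\n")
        p = tmp_path / "t.swc"
        p.write_text(text)
        tree = mo.read_swc(p)
        assert tree.n == 3
        np.testing.assert_array_equal(tree.parent, [-1, 0, 1])


class TestDendriteSelfProximity:
    def test_resampling_constant_spacing(self):
        xyz = np.array([[0, 0, 0], [3, 0, 0], [7, 0, 0]], float)
        tree = mo.NeuriteTree(xyz=xyz, parent=np.array([-1, 0, 1]))
        arbor = mo.resample_tree(tree, 0.5)
        assert len(arbor.xyz) == 14  # 7 um at 0.5 um spacing
        gaps = np.diff(arbor.soma_dist)
        np.testing.assert_allclose(gaps, 0.5)

    def test_single_branch_no_nearby_branches(self):
        xyz = np.column_stack([np.arange(21) * 1.0, np.zeros(21), np.zeros(21)])
        tree = mo.NeuriteTree(xyz=xyz, parent=np.arange(-1, 20))
        counts = mo.dendrite_self_proximity(tree)
        np.testing.assert_array_equal(counts, np.zeros(10))

    def test_parallel_branches_threshold_switch(self, parallel_branch_tree):
        # 3 um apart: within a 5 um radius but not a 2 um radius
        at5 = mo.dendrite_self_proximity(parallel_branch_tree, threshold=5.0)
        at2 = mo.dendrite_self_proximity(parallel_branch_tree, threshold=2.0)
        np.testing.assert_array_equal(at5[1:], np.ones(9))
        np.testing.assert_array_equal(at2[1:], np.zeros(9))

    def test_tiny_tree_fewer_bins_with_warning(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        tree = mo.NeuriteTree(xyz=xyz, parent=np.array([-1, 0, 1]))
        with pytest.warns(UserWarning):
            counts = mo.dendrite_self_proximity(tree, node_spacing=1.0,
                                                n_bins=10)
        assert len(counts) < 10
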