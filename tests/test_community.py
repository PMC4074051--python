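"""Idealized-tree UniFrac, ordination, PERMANOVA and Welch screening."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.diversity.beta import weighted_unifrac as skbio_weighted_unifrac
from skbio.stats.distance import permanova as skbio_permanova

import phylospectra as ps

from conftest import make_eotu_table

RANKS7 = ["Dom", "Phy", "Cls", "Ord", "Fam", "Gen", "Sp"]


def random_lineages(rng, n_leaves):
    """Random truncated rank paths over a tiny alphabet (shared prefixes arise)."""
    out = {}
    for i in range(n_leaves):
        depth = rng.integers(1, 5)
        out[f"L{i}"] = [f"r{d}{rng.integers(0, 2)}" for d in range(depth)]
    return out


def unifrac_oracle(ab, tree, normalized):
    """Explicit branch enumeration, independent of the postorder implementation."""
    totals = ab.sum(axis=0)
    props = ab.div(totals, axis=1)
    samples = list(ab.columns)
    dist = np.zeros((len(samples), len(samples)))
    branches = []
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length, leaves))
    for i, j in itertools.combinations(range(len(samples)), 2):
        raw = denom = 0.0
        for length, leaves in branches:
            pi = props.loc[list(leaves), samples[i]].sum()
            pj = props.loc[list(leaves), samples[j]].sum()
            raw += length * abs(pi - pj)
            denom += length * (pi + pj)
        d = raw / denom if normalized and denom > 0 else (0.0 if normalized else raw)
        dist[i, j] = dist[j, i] = d
    return dist


class TestIdealizedTree:
    def test_identical_lineages_become_siblings(self):
        tree = ps.build_idealized_tree({"A": RANKS7, "B": RANKS7})
        a, b = tree.find("A"), tree.find("B")
        assert a.parent is b.parent and a.parent.name == "Sp"
        assert a.distance(b) == 2.0

    def test_divergence_after_three_shared_ranks(self):
        lin_a = RANKS7[:3] + ["OrdA", "FamA", "GenA", "SpA"]
        lin_b = RANKS7[:3] + ["OrdB", "FamB", "GenB", "SpB"]
        tree = ps.build_idealized_tree({"A": lin_a, "B": lin_b})
        assert tree.find("A").distance(tree.find("B")) == 10.0

    def test_single_eotu_chain_and_zero_self_distance(self):
        tree = ps.build_idealized_tree({"A": RANKS7})
        assert tree.find("A").distance(tree) == 8.0
        ab = pd.DataFrame({"s1": [2.0], "s2": [5.0]}, index=["A"])
        dm = ps.weighted_unifrac(ab, tree)
        assert dm["s1", "s2"] == 0.0

    def test_truncated_lineage_leaf_depth(self):
        tree = ps.build_idealized_tree({"A": ["Dom", "Phy"], "B": RANKS7})
        assert tree.find("A").distance(tree) == 3.0

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError):
            ps.build_idealized_tree({"A": []})


class TestWeightedUnifrac:
    def test_identical_profiles_give_zero(self):
        tree = ps.build_idealized_tree({"A": ["x"], "B": ["y"]})
        ab = pd.DataFrame({"s1": [3.0, 1.0], "s2": [6.0, 2.0]}, index=["A", "B"])
        dm = ps.weighted_unifrac(ab, tree, normalized=False)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_summed_three_leaf_example(self):
        # ((A,B),C) as a rank tree: A,B under x; C one rank deep under y
        tree = ps.build_idealized_tree({"A": ["x"], "B": ["x"], "C": ["y"]})
        ab = pd.DataFrame({"s1": [1.0, 0.0, 0.0], "s2": [0.0, 0.0, 1.0]}, index=["A", "B", "C"])
        raw = ps.weighted_unifrac(ab, tree, normalized=False)
        # branches: leaf A (1), leaf B (0), x (1), y-chain to C (2)
        assert raw["s1", "s2"] == pytest.approx(4.0)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_branch_enumeration_oracle(self, normalized):
        rng = np.random.default_rng(42)
        for _ in range(40):
            lineages = random_lineages(rng, int(rng.integers(2, 7)))
            tree = ps.build_idealized_tree(lineages)
            n_s = int(rng.integers(2, 5))
            ab = pd.DataFrame(
                rng.random((len(lineages), n_s)) * (rng.random((len(lineages), n_s)) > 0.3),
                index=list(lineages),
                columns=[f"s{j}" for j in range(n_s)],
            )
            ab += 1e-9  # keep all sample totals positive
            got = ps.weighted_unifrac(ab, tree, normalized=normalized)
            expected = unifrac_oracle(ab, tree, normalized)
            np.testing.assert_allclose(got.data, expected, atol=1e-10)

    def test_matches_skbio_reference(self):
        lineages = {"A": ["x", "q"], "B": ["x", "r"], "C": ["y"], "D": ["y", "z", "w"]}
        tree = ps.build_idealized_tree(lineages)
        ab = pd.DataFrame({"s1": [5.0, 1, 0, 2], "s2": [0.0, 3, 4, 1]}, index=list("ABCD"))
        for normalized in (False, True):
            mine = ps.weighted_unifrac(ab, tree, normalized=normalized)["s1", "s2"]
            ref = skbio_weighted_unifrac(
                ab["s1"].to_numpy(), ab["s2"].to_numpy(),
                taxa=list("ABCD"), tree=tree, normalized=normalized,
            )
            assert mine == pytest.approx(float(ref), abs=1e-12)

    def test_normalized_bounded_and_consistent_with_raw(self):
        rng = np.random.default_rng(7)
        lineages = random_lineages(rng, 5)
        tree = ps.build_idealized_tree(lineages)
        ab = pd.DataFrame(
            rng.random((5, 4)) + 0.01, index=list(lineages), columns=list("wxyz")
        )
        norm = ps.weighted_unifrac(ab, tree, normalized=True)
        assert (norm.data >= 0).all() and (norm.data <= 1 + 1e-12).all()

    def test_all_zero_sample_rejected(self):
        tree = ps.build_idealized_tree({"A": ["x"], "B": ["y"]})
        ab = pd.DataFrame({"s1": [1.0, 1.0], "s2": [0.0, 0.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            ps.weighted_unifrac(ab, tree)


def upgma_oracle(d, labels):
    """Naive UPGMA recomputation: merge closest clusters, average distances."""
    clusters = {i: [i] for i in range(len(labels))}
    dist = {frozenset((i, j)): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    heights = []
    nxt = len(labels)
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k], sorted(k)))
        i, j = sorted(pair)
        h = dist[pair]
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        new_dist = {}
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        for k, members in clusters.items():
            s = sum(
                d[a, b] for a in merged for b in members
            )
            new_dist[frozenset((nxt, k))] = s / (len(merged) * len(members))
        clusters[nxt] = merged
        dist.update(new_dist)
        nxt += 1
    return heights


class TestHierarchicalCluster:
    def test_two_samples_single_merge(self):
        dm = DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["a", "b"])
        Z, labels = ps.hierarchical_cluster(dm)
        assert Z.shape == (1, 4) and Z[0, 2] == 3.0

    def test_unambiguous_three_sample_order(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        dm = DistanceMatrix(d, ids=["A", "B", "C"])
        Z, labels = ps.hierarchical_cluster(dm)
        assert Z[0, 2] == 1.0 and Z[1, 2] == 10.0

    def test_merge_heights_match_upgma_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        Z, labels = ps.hierarchical_cluster(dm)
        expected = upgma_oracle(d, labels)
        np.testing.assert_allclose(Z[:, 2], expected, rtol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.hierarchical_cluster(DistanceMatrix([[0.0]], ids=["a"]))


class TestNMDS:
    def planar_dm(self, seed, n=5):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=[f"p{i}" for i in range(n)])

    def test_planar_points_embed_with_negligible_stress(self):
        res = ps.nmds(self.planar_dm(0), k=2, n_restarts=5, seed=0)
        assert res.stress < 0.01

    def test_equilateral_three_points(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = ps.nmds(dm, k=2, n_restarts=5, seed=0)
        assert res.stress < 0.01

    def test_stress_nearly_invariant_under_monotone_transform(self):
        for seed in range(10):
            dm = self.planar_dm(100 + seed, n=6)
            res1 = ps.nmds(dm, k=2, n_restarts=5, seed=1)
            dm2 = DistanceMatrix(dm.data**2, ids=dm.ids)  # strictly increasing transform
            res2 = ps.nmds(dm2, k=2, n_restarts=5, seed=1)
            assert abs(res1.stress - res2.stress) < 0.05

    def test_stress_monotone_within_restart(self):
        dm = self.planar_dm(3, n=7)
        res = ps.nmds(dm, k=2, n_restarts=3, seed=2)
        h = res.stress_history
        assert all(a >= b - 1e-8 for a, b in zip(h, h[1:]))

    def test_stress_in_unit_interval(self):
        res = ps.nmds(self.planar_dm(5, n=6), k=1, n_restarts=3, seed=0)
        assert 0.0 <= res.stress <= 1.0

    def test_too_many_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ps.nmds(self.planar_dm(0, n=3), k=3)


def separated_fixture():
    d = np.ones((6, 6))
    d[:3, :3] = 0
    d[3:, 3:] = 0
    np.fill_diagonal(d, 0)
    dm = DistanceMatrix(d, ids=list("abcdef"))
    groups = pd.Series({s: ("g1" if s in "abc" else "g2") for s in "abcdef"})
    return dm, groups


class TestPermanova:
    def test_separated_clusters_exhaustive_p(self):
        dm, groups = separated_fixture()
        res = ps.permanova(dm, groups, n_perm=999, seed=0)
        assert res.exhaustive and res.n_permutations == 20
        assert res.p_value == pytest.approx(0.1)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(8)]
        groups = pd.Series({s: ("a" if i < 4 else "b") for i, s in enumerate(ids)})
        dm = DistanceMatrix(d, ids=ids)
        perm = [3, 7, 0, 5, 1, 6, 2, 4]
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        r1 = ps.permanova(dm, groups, n_perm=99, seed=5)
        r2 = ps.permanova(dm2, groups, n_perm=99, seed=5)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value)  # both exhaustive (70 <= 99)

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((10, 3))
        pts[:5] += 1.5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(10)]
        dm = DistanceMatrix(d, ids=ids)
        groups = pd.Series({s: ("a" if i < 5 else "b") for i, s in enumerate(ids)})
        mine = ps.permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, groups.loc[ids].to_numpy(), permutations=99)
        assert mine.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_singleton_group_rejected(self):
        dm, groups = separated_fixture()
        groups["a"] = "g3"
        with pytest.raises(ValueError):
            ps.permanova(dm, groups, n_perm=99)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = ps.welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_derived_example(self):
        t, df, p = ps.welch_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_swap_symmetry(self):
        t1, _, p1 = ps.welch_test([1, 5, 2], [4, 8, 9])
        t2, _, p2 = ps.welch_test([4, 8, 9], [1, 5, 2])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_conventions(self):
        t, _, p = ps.welch_test([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        with pytest.warns(UserWarning):
            t, _, p = ps.welch_test([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0


class TestScreens:
    samples = [f"S{i}" for i in range(8)]
    groups = pd.Series(
        {f"S{i}": ("a" if i < 4 else "b") for i in range(8)}
    )

    def test_identical_group_profiles_flag_nothing(self):
        # both groups see the same values per eOTU -> t = 0, p = 1 everywhere
        hyb = np.tile([7.0, 8.0, 9.0, 10.0, 7.0, 8.0, 9.0, 10.0], (5, 1))
        t = make_eotu_table(5, self.samples, hyb)
        out = ps.eotu_screen(t, self.groups)
        assert out["significant"].sum() == 0
        assert (out["p_value"] == 1.0).all()

    def test_single_eotu_matches_direct_welch(self):
        rng = np.random.default_rng(1)
        hyb = rng.normal(8, 1, (1, 8))
        t = make_eotu_table(1, self.samples, hyb)
        out = ps.eotu_screen(t, self.groups)
        tt, df, p = ps.welch_test(hyb[0, :4], hyb[0, 4:])
        assert out["p_value"].iloc[0] == pytest.approx(p)
        assert out["t"].iloc[0] == pytest.approx(tt)

    def test_known_shifts_detected_and_false_positive_rate_calibrated(self):
        # 10 samples per group keeps the Welch approximation close to nominal size
        n_seeds, m, shifted = 40, 100, 10
        samples = [f"S{i}" for i in range(20)]
        groups = pd.Series({s: ("a" if i < 10 else "b") for i, s in enumerate(samples)})
        fp_total = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            hyb = rng.normal(8, 1, (m, 20))
            hyb[:shifted, 10:] += 6.0
            t = make_eotu_table(m, samples, hyb)
            out = ps.eotu_screen(t, groups, alpha=0.05)
            assert out["significant"].iloc[:shifted].all()
            fp_total += int(out["significant"].iloc[shifted:].sum())
        null_tests = n_seeds * (m - shifted)
        rate = fp_total / null_tests
        se = math.sqrt(0.05 * 0.95 / null_tests)
        assert abs(rate - 0.05) <= 3 * se

    def test_family_aggregation_matches_groupby_sum(self):
        rng = np.random.default_rng(2)
        hyb = rng.normal(8, 1, (12, 8))
        t = make_eotu_table(12, self.samples, hyb, n_families=3)
        out = ps.family_aggregate_screen(t, self.groups)
        assert len(out) == 3
        # brute-force re-aggregation per family
        for f in range(3):
            members = [i for i in range(12) if i % 3 == f]
            agg = hyb[members].sum(axis=0)
            tt, df, p = ps.welch_test(agg[:4], agg[4:])
            assert out.loc[f"Fam{f}", "p_value"] == pytest.approx(p)

    def test_one_eotu_family_equals_eotu_screen(self):
        rng = np.random.default_rng(3)
        hyb = rng.normal(8, 1, (1, 8))
        t = make_eotu_table(1, self.samples, hyb)
        fam = ps.family_aggregate_screen(t, self.groups)
        eot = ps.eotu_screen(t, self.groups)
        assert fam["p_value"].iloc[0] == pytest.approx(eot["p_value"].iloc[0])


class TestPermutationFDR:
    samples = [f"S{i}" for i in range(8)]
    groups = pd.Series({f"S{i}": ("a" if i < 4 else "b") for i in range(8)})

    def test_null_data_calibration(self):
        rng = np.random.default_rng(4)
        hyb = rng.normal(8, 1, (100, 8))
        t = make_eotu_table(100, self.samples, hyb)
        res = ps.permutation_fdr(t, self.groups, n_perm=60, seed=0)
        # expected null count estimates alpha * m
        se = math.sqrt(100 * 0.05 * 0.95 / 60)
        assert abs(res.expected_null_count - 5.0) <= 3 * (se + math.sqrt(100 * 0.05 * 0.95))
        assert res.ratio > 0

    def test_strong_signal_gives_small_ratio(self):
        rng = np.random.default_rng(5)
        hyb = rng.normal(8, 1, (100, 8))
        hyb[:10, 4:] += 6.0
        t = make_eotu_table(100, self.samples, hyb)
        res = ps.permutation_fdr(t, self.groups, n_perm=60, seed=1)
        assert res.observed_count >= 10
        assert res.ratio < 0.5
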