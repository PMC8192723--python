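import io
import itertools
import math

import numpy as np
import pytest

from commvade.diversity import (
    DistanceMatrix,
    alpha_diversity_table,
    beta_diversity_matrix,
    pairwise_permanova,
    permanova,
    pielou,
    richness,
    unweighted_unifrac,
    weighted_unifrac,
)
from commvade.errors import ValidationError
from commvade.phylo import parse_newick
from commvade.synthetic_community import random_coalescent_tree

from conftest import TOY_NEWICK


# --- independent brute-force UniFrac oracle (branch-by-branch enumeration) ---

def enumerate_branches(tree):
    """(length, frozenset of descendant leaves) for every non-root edge."""
    out = []

    def walk(node):
        if node.is_leaf:
            leaves = frozenset([node.name])
        else:
            leaves = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root:
            out.append((node.length or 0.0, leaves))
        return leaves

    walk(tree.root)
    return out


def unweighted_bf(tree, present_a, present_b):
    unique = union = 0.0
    for length, leaves in enumerate_branches(tree):
        ca, cb = bool(leaves & present_a), bool(leaves & present_b)
        if ca or cb:
            union += length
            if ca != cb:
                unique += length
    return unique / union if union else 0.0


def weighted_bf(tree, rel_a, rel_b, normalized):
    raw = denom = 0.0
    for length, leaves in enumerate_branches(tree):
        pa = sum(rel_a.get(x, 0.0) for x in leaves)
        pb = sum(rel_b.get(x, 0.0) for x in leaves)
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    if not normalized:
        return raw
    return raw / denom if denom else 0.0


def random_instance(rng, n_leaves=16):
    leaves = [f"L{i}" for i in range(n_leaves)]
    tree = random_coalescent_tree(leaves, rng)
    a = rng.integers(0, 20, n_leaves)
    b = rng.integers(0, 20, n_leaves)
    a[rng.integers(0, n_leaves)] += 1  # non-empty samples
    b[rng.integers(0, n_leaves)] += 1
    return tree, leaves, a, b


class TestAlpha:
    def test_richness_counts_nonzero(self):
        assert richness([5, 0, 7]) == 2
        assert richness([0, 0]) == 0

    def test_richness_matches_brute_force(self, rng):
        for _ in range(20):
            v = rng.integers(0, 3, 12)
            assert richness(v) == sum(1 for x in v if x > 0)

    def test_pielou_uniform_is_one(self):
        assert pielou([7, 7, 7, 7]) == pytest.approx(1.0)

    def test_pielou_direct_formula(self):
        # H' = -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.5623; J = H'/ln 2
        assert pielou([75, 25]) == pytest.approx(0.8112781, abs=1e-6)

    def test_pielou_single_taxon_undefined(self):
        with pytest.warns(UserWarning):
            assert math.isnan(pielou([10, 0]))

    def test_pielou_bounded_on_random_counts(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=100, derandomize=True)
        @given(st.lists(st.integers(1, 10_000), min_size=2, max_size=30))
        def check(counts):
            j = pielou(counts)
            assert 0.0 <= j <= 1.0 + 1e-12

        check()

    def test_alpha_table(self, default_study):
        df = alpha_diversity_table(default_study.table)
        assert len(df) == default_study.table.shape[0]
        assert (df["richness"] > 0).all()


class TestUniFrac:
    def test_identical_samples_are_zero(self, toy_tree):
        ids = list("ABCD")
        a = np.array([3, 1, 0, 2])
        assert unweighted_unifrac(a, a, toy_tree, ids) == 0.0
        assert weighted_unifrac(a, a, toy_tree, ids) == 0.0

    def test_disjoint_clades_unweighted_is_one(self, toy_tree):
        ids = list("ABCD")
        assert unweighted_unifrac([1, 1, 0, 0], [0, 0, 1, 1], toy_tree, ids) == 1.0

    def test_partial_overlap_enumeration(self, toy_tree):
        # a={A,B}, b={A,C}: unique {B, C, CD} = 3; union = 5 -> 0.6
        assert unweighted_unifrac([1, 1, 0, 0], [1, 0, 1, 0], toy_tree, list("ABCD")) \
            == pytest.approx(0.6)

    def test_weighted_point_masses(self, toy_tree):
        ids = list("ABCD")
        raw = weighted_unifrac([1, 0, 0, 0], [0, 0, 1, 0], toy_tree, ids, normalized=False)
        assert raw == pytest.approx(4.0)
        assert weighted_unifrac([1, 0, 0, 0], [0, 0, 1, 0], toy_tree, ids) == 1.0

    def test_star_tree_weighted_is_l1(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        p = np.array([6, 3, 1])
        q = np.array([2, 2, 6])
        raw = weighted_unifrac(p, q, tree, list("ABC"), normalized=False)
        l1 = np.abs(p / p.sum() - q / q.sum()).sum()
        assert raw == pytest.approx(l1)

    def test_unweighted_ignores_abundance(self, toy_tree):
        ids = list("ABCD")
        d1 = unweighted_unifrac([1, 9, 0, 0], [1, 0, 4, 0], toy_tree, ids)
        d2 = unweighted_unifrac([90, 2, 0, 0], [5, 0, 1, 0], toy_tree, ids)
        assert d1 == d2

    def test_missing_leaf_is_named(self, toy_tree):
        with pytest.raises(ValidationError, match="ZZ"):
            unweighted_unifrac([1], [1], toy_tree, ["ZZ"])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            tree, ids, a, b = random_instance(rng)
            pa = {x: v for x, v in zip(ids, a / a.sum()) if v > 0}
            pb = {x: v for x, v in zip(ids, b / b.sum()) if v > 0}
            sa = frozenset(x for x, v in zip(ids, a) if v > 0)
            sb = frozenset(x for x, v in zip(ids, b) if v > 0)
            assert unweighted_unifrac(a, b, tree, ids) == pytest.approx(
                unweighted_bf(tree, sa, sb), abs=1e-9
            )
            for norm in (True, False):
                assert weighted_unifrac(a, b, tree, ids, normalized=norm) == \
                    pytest.approx(weighted_bf(tree, pa, pb, norm), abs=1e-9)

    def test_matches_reference_implementation(self, rng):
        """Agreement with scikit-bio (reference only) on 50 random instances."""
        import skbio
        from skbio.diversity.beta import (
            unweighted_unifrac as sk_u,
            weighted_unifrac as sk_w,
        )

        for _ in range(50):
            tree, ids, a, b = random_instance(rng, n_leaves=12)
            sk_tree = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
            assert unweighted_unifrac(a, b, tree, ids) == pytest.approx(
                sk_u(a, b, taxa=ids, tree=sk_tree), abs=1e-9
            )
            assert weighted_unifrac(a, b, tree, ids, normalized=True) == pytest.approx(
                sk_w(a, b, taxa=ids, tree=sk_tree, normalized=True), abs=1e-9
            )
            assert weighted_unifrac(a, b, tree, ids, normalized=False) == pytest.approx(
                sk_w(a, b, taxa=ids, tree=sk_tree, normalized=False), abs=1e-9
            )

    def test_distance_matrix_round_trip(self, tmp_path, default_study):
        sub_ids = default_study.table.sample_ids[:6]
        idx = [default_study.table.sample_ids.index(s) for s in sub_ids]
        from commvade.tables_io import AsvCountTable

        sub = AsvCountTable(
            sub_ids, default_study.table.asv_ids, default_study.table.counts[idx]
        )
        dm = beta_diversity_matrix(sub, default_study.tree, "unifrac-w")
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.sample_ids == dm.sample_ids
        assert np.allclose(back.values, dm.values)


def euclidean_dm(points, ids=None):
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(ids or [f"S{i}" for i in range(n)], d)


def pseudo_f_reference(d, labels):
    """Straight transcription of the SS partition, kept independent."""
    n = len(labels)
    d2 = d**2
    ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(labels):
        members = [i for i, l in enumerate(labels) if l == g]
        ss_w += sum(
            d2[i, j] for i in members for j in members if i < j
        ) / len(members)
    a = len(set(labels))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def test_coincident_groups_give_infinite_f(self, rng):
        pts = np.array([[0.0, 0]] * 8 + [[5.0, 0]] * 8)
        labels = ["a"] * 8 + ["b"] * 8
        res = permanova(euclidean_dm(pts), labels, 999, seed=11)
        assert math.isinf(res.pseudo_F)
        assert res.R2 == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_exhaustive_enumeration_small_n(self, rng):
        """999 random permutations agree with all 20 exact splits at n=6."""
        pts = rng.normal(size=(6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d = euclidean_dm(pts)
        res = permanova(d, labels, 999, seed=5)
        f_obs = pseudo_f_reference(d.values, list(labels))
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-9)
        hits = 0
        for combo in itertools.combinations(range(6), 3):
            perm = np.array(["b"] * 6)
            perm[list(combo)] = "a"
            if pseudo_f_reference(d.values, list(perm)) >= f_obs - 1e-12:
                hits += 1
        exact_p = hits / 20
        assert abs(res.p_perm - exact_p) <= 0.05

    def test_seeded_reproducibility(self, rng):
        pts = rng.normal(size=(12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(euclidean_dm(pts), labels, 199, seed=3)
        r2 = permanova(euclidean_dm(pts), labels, 199, seed=3)
        assert (r1.pseudo_F, r1.p_perm) == (r2.pseudo_F, r2.p_perm)

    def test_relabelling_invariance_of_f(self, rng):
        pts = rng.normal(size=(10, 2))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        order = rng.permutation(10)
        d = euclidean_dm(pts)
        ids = [d.sample_ids[i] for i in order]
        r1 = permanova(d, labels, 199, seed=1)
        r2 = permanova(d.submatrix(ids), labels[order], 199, seed=1)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.R2 == pytest.approx(r2.R2)

    def test_matches_skbio_statistic(self, rng):
        import skbio

        pts = rng.normal(size=(15, 3))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        d = euclidean_dm(pts)
        res = permanova(d, labels, 99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.sample_ids), grouping=labels,
            permutations=99,
        )
        assert res.pseudo_F == pytest.approx(sk["test statistic"], abs=1e-9)

    def test_all_zero_distances_flagged_degenerate(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        res = permanova(dm, ["x", "x", "y", "y"], 99, seed=0)
        assert res.degenerate
        assert math.isnan(res.p_perm)


class TestPairwisePermanova:
    def test_row_count_is_choose_two(self, rng):
        pts = rng.normal(size=(12, 2))
        labels = ["a", "b", "c", "d"] * 3
        df = pairwise_permanova(euclidean_dm(pts), labels, 99, seed=0)
        assert len(df) == 6

    def test_identical_groups_not_significant(self):
        pts = np.array([[float(i % 3), 0] for i in range(9)])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        # make each group contain the same three points
        pts = np.array([[0.0, 0], [1, 0], [2, 0]] * 3)
        df = pairwise_permanova(euclidean_dm(pts), labels, 199, seed=0)
        assert (df["p_adjusted"] > 0.9).all()

    def test_bonferroni_arithmetic(self, rng):
        pts = np.vstack(
            [rng.normal(0, 1, (4, 2)), rng.normal(5, 1, (4, 2)), rng.normal(10, 1, (4, 2))]
        )
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        df = pairwise_permanova(euclidean_dm(pts), labels, 199, seed=2, adjust="bonferroni")
        expected = np.minimum(1.0, df["p_raw"] * len(df))
        assert np.allclose(df["p_adjusted"], expected)
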