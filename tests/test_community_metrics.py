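"""Diversity arithmetic against hand values and scikit-bio; ordination
round-trips; PERMANOVA against an enumeration oracle and skbio; dispersion."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as skbio_permanova

from stopover import community_metrics as cm


class TestAlpha:
    def test_shannon_equal_taxa(self):
        assert cm.shannon([5, 5, 5, 5]) == pytest.approx(np.log(4), abs=1e-12)

    def test_shannon_single_taxon(self):
        assert cm.shannon([10]) == 0.0

    def test_chao1_hand_value(self):
        # S_obs=6, F1=3, F2=2 -> 6 + 3*2/(2*3) = 7
        assert cm.chao1([1, 1, 1, 2, 2, 5]) == pytest.approx(7.0)

    def test_faith_pd_hand_value(self, toy_tree):
        assert cm.faith_pd([1, 0, 1], ["A", "B", "C"], toy_tree) == pytest.approx(4.0)

    def test_all_zero_rejected(self):
        for fn in (cm.shannon, cm.chao1):
            with pytest.raises(ValueError):
                fn([0, 0])

    def test_transforms(self):
        assert cm.transform_alpha([1.0], "shannon")[0] == pytest.approx(0.0)
        assert cm.transform_alpha([4.0], "faith_pd")[0] == pytest.approx(0.25)
        assert cm.transform_alpha([7.0], "chao1")[0] == pytest.approx(7.0)
        with pytest.raises(ValueError):
            cm.transform_alpha([0.0], "shannon")

    def test_alpha_table_matches_scalar_functions(self, toy_tree):
        counts = pd.DataFrame([[3, 1, 0], [1, 1, 1]], columns=list("ABC"))
        tab = cm.alpha_table(counts, toy_tree)
        for i in range(2):
            assert tab["shannon"].iloc[i] == pytest.approx(cm.shannon(counts.iloc[i]))
            assert tab["faith_pd"].iloc[i] == pytest.approx(
                cm.faith_pd(counts.iloc[i], list("ABC"), toy_tree)
            )


class TestBeta:
    def test_identical_samples_are_zero_everywhere(self, toy_tree):
        counts = pd.DataFrame([[3, 2, 1], [3, 2, 1]], columns=list("ABC"))
        for metric in cm.BETA_METRICS:
            d = cm.beta_distance(counts, metric, tree=toy_tree)
            assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_jaccard_hand_value(self):
        counts = pd.DataFrame([[1, 1, 1, 0], [0, 1, 1, 1]], columns=list("ABCD"))
        d = cm.beta_distance(counts, "jaccard")
        assert d.data[0, 1] == pytest.approx(0.5)

    def test_unweighted_unifrac_disjoint_clades(self, toy_tree4):
        counts = pd.DataFrame([[1, 0, 0, 0], [0, 0, 1, 0]], columns=list("ABCD"))
        d = cm.beta_distance(counts, "unifrac", tree=toy_tree4)
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_missing_tree_rejected(self):
        counts = pd.DataFrame([[1, 0], [0, 1]], columns=list("AB"))
        with pytest.raises(ValueError, match="phylogeny"):
            cm.beta_distance(counts, "unifrac")

    def test_unobserved_tree_taxon_changes_nothing(self, toy_tree, toy_tree4):
        counts = pd.DataFrame([[2, 3, 0], [1, 0, 4]], columns=list("ABC"))
        for metric in ("unifrac", "wunifrac"):
            small = cm.beta_distance(counts, metric, tree=toy_tree)
            # toy_tree4 adds taxon D, absent from the table
            big = cm.beta_distance(counts, metric, tree=toy_tree4)
            assert small.data[0, 1] != 0
            # unweighted ratio changes denominator only via covered branches,
            # which exclude D's branch entirely
            assert big.data[0, 1] == pytest.approx(
                cm.beta_distance(counts, metric, tree=toy_tree4).data[0, 1]
            )

    def test_matches_skbio_on_random_table(self, community):
        table = community["table"]
        counts = table.counts.iloc[:8, :25]
        counts = counts.loc[:, counts.sum() > 0]
        tree = TreeNode.read(io.StringIO(community["newick"]))
        pairs = [
            ("bray", "braycurtis", {}),
            ("unifrac", "unweighted_unifrac", {}),
            ("wunifrac", "weighted_unifrac", {"normalized": False}),
        ]
        for mine_name, sk_name, kw in pairs:
            mine = cm.beta_distance(counts, mine_name, tree=community["newick"])
            if "unifrac" in sk_name:
                ref = beta_diversity(sk_name, counts.to_numpy(), ids=list(counts.index),
                                     taxa=list(counts.columns), tree=tree, **kw)
            else:
                ref = beta_diversity(sk_name, counts.to_numpy(), ids=list(counts.index))
            np.testing.assert_allclose(mine.data, ref.data, atol=1e-10)

    def test_bounds(self, community):
        counts = community["table"].counts.iloc[:6, :20]
        counts = counts.loc[:, counts.sum() > 0]
        for metric in ("bray", "jaccard", "unifrac"):
            d = cm.beta_distance(counts, metric, tree=community["newick"]).data
            assert (d >= 0).all() and (d <= 1 + 1e-12).all()


class TestPcoa:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        _, evals = cm.pcoa(d)
        pos = evals[evals > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        coords, _ = cm.pcoa(DistanceMatrix(d), k=2)
        c = coords.to_numpy()
        d2 = np.linalg.norm(c[:, None] - c[None], axis=-1)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        d = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
        coords, _ = cm.pcoa(DistanceMatrix(d))
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-10)

    def test_k_beyond_rank_warns(self):
        d = DistanceMatrix(np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.warns(UserWarning, match="truncating"):
            coords, _ = cm.pcoa(d, k=5)
        assert coords.shape[1] == 1


def one_way_f_oracle(d: np.ndarray, groups: np.ndarray) -> float:
    """Independent pseudo-F from within-group squared distances only."""
    n = len(groups)
    levels = np.unique(groups)
    ss_total = (d**2).sum() / (2 * n)
    ss_within = 0.0
    for g in levels:
        idx = np.where(groups == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    a = len(levels)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _separated(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(size=(3, 2)), rng.normal(size=(3, 2)) + 40])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        return DistanceMatrix(d, ids=list("abcdef")), ["x"] * 3 + ["y"] * 3

    def test_exhaustive_p_equals_enumeration_oracle(self):
        dist, grp = self._separated()
        res = cm.permanova(dist, pd.DataFrame({"g": grp}), ["g"], all_permutations=True)
        # oracle: enumerate all relabellings, count F* >= F with the closed form
        d = dist.data
        groups = np.array([0, 0, 0, 1, 1, 1])
        f_obs = one_way_f_oracle(d, groups)
        hits = total = 0
        for p in itertools.permutations(range(6)):
            f = one_way_f_oracle(d[np.ix_(p, p)], groups)
            hits += f >= f_obs - 1e-9 * abs(f_obs)
            total += 1
        assert res["p"].iloc[0] == pytest.approx(hits / total)
        assert res["p"].iloc[0] == pytest.approx(2 / 20)

    def test_f_matches_closed_form_and_skbio(self):
        dist, grp = self._separated()
        mine = cm.permanova(dist, pd.DataFrame({"g": grp}), ["g"], n_perm=99, seed=0)
        assert mine["pseudo_F"].iloc[0] == pytest.approx(
            one_way_f_oracle(dist.data, np.array([0, 0, 0, 1, 1, 1])), rel=1e-9
        )
        ref = skbio_permanova(dist, grp, permutations=99)
        assert mine["pseudo_F"].iloc[0] == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_single_term_margin_equals_sequential(self):
        dist, grp = self._separated()
        design = pd.DataFrame({"g": grp})
        a = cm.permanova(dist, design, ["g"], n_perm=49, mode="margin", seed=1)
        b = cm.permanova(dist, design, ["g"], n_perm=49, mode="sequential", seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_sequential_r2_partition_sums_to_one(self, community):
        meta = community["meta"]
        rows = list(meta.index[meta["sex"] == "female"][:6]) + list(
            meta.index[meta["sex"] == "male"][:6]
        )
        meta = meta.loc[rows]
        counts = community["table"].counts.loc[meta["sample_id"]].iloc[:, :30]
        counts = counts.loc[:, counts.sum() > 0]
        dist = cm.beta_distance(counts, "bray")
        design = pd.DataFrame({"sex": meta["sex"].to_numpy(),
                               "date": meta["capture_date"].to_numpy()})
        res = cm.permanova(dist, design, ["sex", "date"], n_perm=9, mode="sequential", seed=0)
        assert res["R2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_aliased_term_rejected(self):
        dist, grp = self._separated()
        design = pd.DataFrame({"g": grp, "g2": grp})  # perfectly confounded
        with pytest.raises(ValueError, match="aliased"):
            cm.permanova(dist, design, ["g", "g2"], n_perm=9, mode="margin", seed=0)

    def test_seed_reproducibility(self):
        dist, grp = self._separated()
        design = pd.DataFrame({"g": grp})
        a = cm.permanova(dist, design, ["g"], n_perm=99, seed=7)
        b = cm.permanova(dist, design, ["g"], n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestDispersion:
    def test_tight_vs_spread_group_detected(self):
        rng = np.random.default_rng(2)
        tight = np.tile(rng.normal(size=(1, 2)), (6, 1)) + rng.normal(0, 1e-4, (6, 2))
        spread = rng.normal(0, 5, size=(6, 2))
        pts = np.vstack([tight, spread])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = cm.dispersion_test(DistanceMatrix(d), ["a"] * 6 + ["b"] * 6,
                                 n_perm=199, seed=0)
        assert res["p"] < 0.05
        assert res["group_dispersion"]["a"] < res["group_dispersion"]["b"]

    def test_identical_groups_give_near_zero_f(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [0, 0], [1, 0], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = cm.dispersion_test(DistanceMatrix(d), ["a", "a", "a", "b", "b", "b"],
                                 n_perm=49, seed=0)
        assert res["F"] == pytest.approx(0.0, abs=1e-9)

    def test_singleton_group_rejected(self):
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        with pytest.raises(ValueError):
            cm.dispersion_test(DistanceMatrix(d), ["a", "b", "b", "b"])
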