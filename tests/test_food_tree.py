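"""Food tree construction, UniFrac distances and the meat/plant ratio."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from dietmg.food_tree import (
    build_food_tree,
    diet_profiles,
    meat_plant_log2ratio,
    unifrac_matrix,
    unweighted_unifrac,
)


def brute_force_unifrac(p_leaves, q_leaves, tree):
    """Independent oracle: enumerate every branch, classify it as shared or
    unique by whether any leaf below it belongs to each profile."""
    p_leaves, q_leaves = set(p_leaves), set(q_leaves)
    unique = total = 0.0
    for node in tree.tree.postorder(include_self=False):
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        in_p = bool(below & p_leaves)
        in_q = bool(below & q_leaves)
        if not (in_p or in_q):
            continue
        length = node.length or 0.0
        total += length
        if in_p != in_q:
            unique += length
    return unique / total


class TestTreeStructure:
    def test_leaves_cover_items_exactly_once(self, food_db, tree):
        leaves = tree.leaves
        assert sorted(leaves) == sorted(food_db.index)
        assert len(leaves) == len(set(leaves))

    def test_every_leaf_is_five_levels_below_root(self, tree):
        for tip in tree.tree.tips():
            depth = 0
            node = tip
            while node.parent is not None:
                depth += 1
                node = node.parent
            assert depth == 5  # L2, L3, L4, L5, leaf

    def test_level5_nodes_nonempty_and_singletons_get_one_child(self, food_db, tree):
        assert tree.n_level5() >= food_db["level4"].nunique()
        singles = food_db.groupby("level4").size()
        for cat in singles[singles == 1].index:
            item = food_db.index[food_db["level4"] == cat][0]
            assert tree.level5_of[item].endswith("n1")

    def test_three_planted_nutrient_clusters_give_three_level5_nodes(self):
        # a cheese-like category: high-fat, low-fat and whey-based profiles
        rng = np.random.default_rng(0)
        centers = np.array([[25, 30, 2, 0], [28, 8, 3, 0], [8, 2, 12, 0]], float)
        rows = []
        for ci, c in enumerate(centers):
            for j in range(4):
                jitter = rng.normal(1, 0.03, size=4)
                rows.append(np.maximum(c * jitter, 0))
        db = pd.DataFrame(rows, columns=["protein_g", "fat_g", "carb_g", "fiber_g"])
        db["level2"] = "animal-based"
        db["level3"] = "animal-based:dairy"
        db["level4"] = "dairy:cheese"
        db["energy_kcal"] = 100.0
        db["is_drink"] = False
        db["fruit_veg_pct"] = 0.0
        db.index = [f"cheese{i}" for i in range(len(db))]
        t = build_food_tree(db, dmm_k_range=[1, 2, 3], seed=1)
        assert t.n_level5() == 3

    def test_missing_level2_raises_listing_items(self, food_db):
        db = food_db.copy()
        db.loc[db.index[0], "level2"] = "unknown"
        with pytest.raises(ValueError, match=db.index[0]):
            build_food_tree(db, seed=0)

    def test_newick_roundtrip(self, tree, tmp_path):
        path = tmp_path / "tree.nwk"
        tree.write_newick(path)
        from skbio import TreeNode

        loaded = TreeNode.read(str(path))
        assert {t.name for t in loaded.tips()} == set(tree.leaves)


class TestUniFrac:
    def test_identity_symmetry_and_disjoint(self, hand_tree):
        a = pd.Series({"a": 1, "b": 0, "c": 0})
        ab = pd.Series({"a": 1, "b": 1, "c": 0})
        c = pd.Series({"a": 0, "b": 0, "c": 1})
        assert unweighted_unifrac(ab, ab, hand_tree) == 0.0
        # a vs c share no branch below the root
        assert unweighted_unifrac(a, c, hand_tree) == 1.0
        assert unweighted_unifrac(a, ab, hand_tree) == unweighted_unifrac(
            ab, a, hand_tree
        )

    def test_hand_tree_value_matches_enumeration(self, hand_tree):
        a = pd.Series({"a": 1, "b": 0, "c": 0})
        ab = pd.Series({"a": 1, "b": 1, "c": 0})
        got = unweighted_unifrac(a, ab, hand_tree)
        # observed branches: a, b, L5, L4, L3, L2 (unit lengths); only b is
        # unique -> 1/6
        assert got == pytest.approx(1 / 6)
        assert got == pytest.approx(brute_force_unifrac({"a"}, {"a", "b"}, hand_tree))

    def test_matches_brute_force_on_random_profiles(self, tree, profiles):
        rng = np.random.default_rng(1)
        idx = rng.choice(len(profiles), size=6, replace=False)
        for i in idx[:3]:
            for j in idx[3:]:
                p, q = profiles.iloc[i], profiles.iloc[j]
                expected = brute_force_unifrac(
                    set(p.index[p > 0]), set(q.index[q > 0]), tree
                )
                assert unweighted_unifrac(p, q, tree) == pytest.approx(expected)

    def test_both_empty_profiles_raise(self, tree):
        empty = pd.Series(0, index=tree.leaves)
        with pytest.raises(ValueError):
            unweighted_unifrac(empty, empty, tree)


class TestUniFracMatrix:
    def test_duplicate_ids_raise(self, profiles, tree):
        dup = pd.concat([profiles.iloc[:2], profiles.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            unifrac_matrix(dup, tree)

    def test_duplicated_diary_gives_zero_distance(self, profiles, tree):
        two = profiles.iloc[[0, 0, 1]].copy()
        two.index = ["x", "y", "z"]
        dm = unifrac_matrix(two, tree)
        assert dm["x", "y"] == 0.0

    def test_row_permutation_permutes_matrix(self, profiles, tree):
        dm = unifrac_matrix(profiles, tree)
        perm = profiles.iloc[::-1]
        dm2 = unifrac_matrix(perm, tree)
        ids = list(profiles.index)
        assert dm2[ids[0], ids[3]] == pytest.approx(dm[ids[0], ids[3]])


class TestMeatPlantRatio:
    def test_all_animal_diary(self, food_db, tree):
        item = food_db.index[food_db["level2"] == "animal-based"][0]
        diary = pd.DataFrame(
            {"subject": ["s"], "day": [1], "meal": ["lunch"], "item": [item], "grams": [100.0]}
        )
        assert meat_plant_log2ratio(diary, tree, pseudocount_g=1.0) == pytest.approx(
            np.log2(101.0), abs=1e-12
        )

    def test_equal_grams_give_zero(self, food_db, tree):
        a = food_db.index[food_db["level2"] == "animal-based"][0]
        p = food_db.index[food_db["level2"] == "plant-based"][0]
        diary = pd.DataFrame(
            {
                "subject": ["s", "s"],
                "day": [1, 1],
                "meal": ["lunch", "lunch"],
                "item": [a, p],
                "grams": [150.0, 150.0],
            }
        )
        assert meat_plant_log2ratio(diary, tree) == 0.0

    def test_planted_gradient_recovered(self, diaries_truth, tree):
        diaries, truth = diaries_truth
        ratios = diaries.groupby("subject").apply(
            lambda g: meat_plant_log2ratio(g, tree), include_groups=False
        )
        rho = spearmanr(
            ratios, truth.subject_latents["meat_plant_score"].loc[ratios.index]
        ).statistic
        assert rho > 0.8

    def test_empty_diary_raises(self, tree):
        with pytest.raises(ValueError):
            meat_plant_log2ratio(pd.DataFrame(columns=["item", "grams"]), tree)


def test_pcoa_axis_correlates_with_meat_plant_ratio(diaries_truth, tree, profiles):
    """The dominant diet ordination axis should track the meat/plant ratio."""
    from dietmg.ordination import pcoa

    diaries, truth = diaries_truth
    dm = unifrac_matrix(profiles, tree)
    res = pcoa(dm)
    ratios = diaries.groupby("subject").apply(
        lambda g: meat_plant_log2ratio(g, tree), include_groups=False
    )
    rhos = [
        abs(spearmanr(res.coords[ax].loc[ratios.index], ratios).statistic)
        for ax in res.coords.columns[:5]
    ]
    assert max(rhos) >= 0.6
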