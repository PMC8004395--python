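"""Nutrient-informed food trees and UniFrac diet distances.

Food items are arranged in a 5-level rooted tree: root (level 1), five large
classes (level 2: animal-based, plant-based, alcohol, fats, others), the food
database hierarchy (levels 3-4), and nutrient subcategories (level 5) found
by splitting each level-4 category with a Dirichlet multinomial mixture over
integerised nutrient compositions.  Diet diaries become binary leaf-presence
profiles (consumed at least once over the 4 days), compared with the
unweighted UniFrac distance; the log2 meat/plant ratio summarises each diary
along the tree's main axis of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.beta import unweighted_unifrac as _skbio_unifrac

from .dmm import fit_dmm

__all__ = [
    "FoodTree",
    "build_food_tree",
    "diet_profiles",
    "unweighted_unifrac",
    "unifrac_matrix",
    "meat_plant_log2ratio",
]

LEVEL2_CLASSES = ("animal-based", "plant-based", "alcohol", "fats", "others")


@dataclass
class FoodTree:
    """Rooted 5-level food tree with items as leaves.

    ``tree`` is a scikit-bio TreeNode whose leaves are food item ids;
    ``level2_of`` maps every item to its level-2 class; ``level5_of`` maps
    every item to its nutrient-subcategory node name.
    """

    tree: TreeNode
    level2_of: dict
    level5_of: dict
    branch_length: float = 1.0
    dmm_fits: dict = field(default_factory=dict, repr=False)

    @property
    def leaves(self):
        return [t.name for t in self.tree.tips()]

    def n_level5(self):
        return len(set(self.level5_of.values()))

    def write_newick(self, path):
        self.tree.write(str(path), format="newick")


def _integerize(nutrients: pd.DataFrame) -> np.ndarray:
    """Round per-100 g nutrient values x10 to integers for the DMM; rows that
    vanish entirely get one pseudo-count so every item stays fittable."""
    counts = np.round(np.asarray(nutrients, dtype=float) * 10.0).astype(int)
    counts = np.maximum(counts, 0)
    zero = counts.sum(axis=1) == 0
    counts[zero, 0] = 1
    return counts


def build_food_tree(
    food_db: pd.DataFrame,
    level2_map=None,
    dmm_k_range=(1, 2, 3),
    seed: int = 0,
    nutrient_cols=None,
    branch_length: float = 1.0,
) -> FoodTree:
    """Build the 5-level food tree from a composition table.

    Every level-4 category with at least two items is split into level-5
    nutrient subcategories by the DMM component assignment (selected by
    minimum Laplace score over ``dmm_k_range``); singleton categories become
    one level-5 node.  Energy is excluded from the composition vector, being
    a linear combination of the macronutrients.

    ``level2_map`` optionally overrides the table's ``level2`` column
    (item -> class); items without a level-2 class raise an error listing
    them.
    """
    db = food_db.copy()
    if level2_map is not None:
        db["level2"] = pd.Series(level2_map).reindex(db.index)
    missing = db.index[~db["level2"].isin(LEVEL2_CLASSES)].tolist()
    if missing:
        raise ValueError(f"items without a valid level-2 class: {missing[:10]}")
    for col in ("level3", "level4"):
        if col not in db.columns or db[col].isna().any():
            raise ValueError(f"every item needs a {col} label")
    if nutrient_cols is None:
        skip = {"energy_kcal", "energy_kj", "fruit_veg_pct", "nutrient_component"}
        nutrient_cols = [
            c for c in db.columns if db[c].dtype.kind in "fi" and c not in skip
        ]

    root = TreeNode(name="root")
    nodes = {}
    level2_of, level5_of, fits = {}, {}, {}

    def child(parent, name):
        if name not in nodes:
            n = TreeNode(name=name, length=branch_length)
            parent.append(n)
            nodes[name] = n
        return nodes[name]

    rng_offset = 0
    for (l2, l3, l4), group in db.groupby(["level2", "level3", "level4"], sort=True):
        n2 = child(root, l2)
        n3 = child(n2, f"L3|{l3}")
        n4 = child(n3, f"L4|{l4}")
        if len(group) >= 2:
            counts = _integerize(group[nutrient_cols])
            ks = [k for k in dmm_k_range if k <= len(group)]
            fit = fit_dmm(counts, ks or [1], seed=seed + rng_offset)
            assign = fit.assignments
            fits[l4] = fit
        else:
            assign = np.zeros(len(group), dtype=int)
        rng_offset += 1
        for item, comp in zip(group.index, assign):
            l5_name = f"L5|{l4}|n{comp + 1}"
            n5 = child(n4, l5_name)
            leaf = TreeNode(name=str(item), length=branch_length)
            n5.append(leaf)
            level2_of[str(item)] = l2
            level5_of[str(item)] = l5_name
    return FoodTree(
        tree=root,
        level2_of=level2_of,
        level5_of=level5_of,
        branch_length=branch_length,
        dmm_fits=fits,
    )


def diet_profiles(diaries: pd.DataFrame, tree: FoodTree) -> pd.DataFrame:
    """Binary subject x leaf presence matrix (any consumption > 0 g across
    the diary days)."""
    leaves = tree.leaves
    consumed = diaries[diaries["grams"] > 0]
    tab = pd.crosstab(consumed["subject"], consumed["item"])
    prof = (tab > 0).astype(int).reindex(columns=leaves, fill_value=0)
    prof.columns.name = None
    return prof


def unweighted_unifrac(p, q, tree: FoodTree) -> float:
    """Unweighted UniFrac between two leaf-presence profiles: the fraction of
    observed branch length unique to one profile."""
    p = pd.Series(p)
    q = pd.Series(q)
    if p.sum() == 0 and q.sum() == 0:
        raise ValueError("both profiles are empty")
    leaves = tree.leaves
    u = p.reindex(leaves, fill_value=0).to_numpy()
    v = q.reindex(leaves, fill_value=0).to_numpy()
    return float(_skbio_unifrac(u, v, taxa=leaves, tree=tree.tree, validate=False))


def unifrac_matrix(profiles: pd.DataFrame, tree: FoodTree) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distance matrix between diet profiles.

    ``profiles`` is the output of :func:`diet_profiles` (subjects x leaves);
    duplicate subject ids raise an error.
    """
    if profiles.index.duplicated().any():
        dupes = profiles.index[profiles.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    counts = profiles.reindex(columns=tree.leaves, fill_value=0).to_numpy()
    if (counts.sum(axis=1) == 0).any():
        empty = profiles.index[counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"empty diet profiles: {empty}")
    # validate=False: the level-1 root legitimately has five level-2 children,
    # which scikit-bio's rooted-tree check would reject; leaf coverage and
    # branch lengths are guaranteed by construction.
    return beta_diversity(
        "unweighted_unifrac",
        counts,
        ids=list(profiles.index),
        tree=tree.tree,
        taxa=tree.leaves,
        validate=False,
    )


def meat_plant_log2ratio(
    diary: pd.DataFrame, tree: FoodTree, pseudocount_g: float = 1.0
) -> float:
    """log2((animal-based grams + pc) / (plant-based grams + pc)) over one
    subject's diary; alcohol, fats and others enter neither sum."""
    if diary.empty:
        raise ValueError("diary is empty")
    l2 = diary["item"].map(tree.level2_of)
    grams = diary["grams"]
    meat = float(grams[l2 == "animal-based"].sum())
    plant = float(grams[l2 == "plant-based"].sum())
    return float(np.log2((meat + pseudocount_g) / (plant + pseudocount_g)))
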