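"""Build a nutrient-informed food tree and compare diet diaries with UniFrac.

Generates a synthetic food composition table and 4-day diaries for a small
cohort, builds the 5-level food tree (level 5 = nutrient subcategories found
by Dirichlet multinomial mixtures), computes pairwise unweighted UniFrac
distances between subjects' diet profiles and ordinates them with PCoA.
"""

from scipy.stats import spearmanr

from dietmg.food_tree import (
    build_food_tree,
    diet_profiles,
    meat_plant_log2ratio,
    unifrac_matrix,
)
from dietmg.ordination import pcoa
from dietmg.synthetic_data import gen_diaries, gen_food_db

food_db = gen_food_db(n_items=120, n_nutrients=8, seed=1)
diaries, truth = gen_diaries(food_db, n_subjects=40, gradient_sd=1.0, seed=2)
tree = build_food_tree(food_db, seed=3)

print(f"food tree: {len(tree.leaves)} items in {tree.n_level5()} level-5 subcategories")

profiles = diet_profiles(diaries, tree)
dm = unifrac_matrix(profiles, tree)
res = pcoa(dm)
print(
    "diet PCoA: axis 1 explains "
    f"{res.proportion_explained[0]:.1%}, axis 2 {res.proportion_explained[1]:.1%}"
)

ratios = diaries.groupby("subject").apply(
    lambda g: meat_plant_log2ratio(g, tree), include_groups=False
)
rho = spearmanr(res.coords["PCo1"].loc[ratios.index], ratios).statistic
print(f"Spearman rho between PCoA axis 1 and log2 meat/plant ratio: {rho:+.2f}")
print(
    "-> the dominant axis of dietary variation separates meat-leaning from "
    "plant-leaning subjects, as planted by the generator's latent gradient"
)
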