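"""CAZy-hydrogenase correlation network, LDA severity ranking and CAZotypes.

Generates gene-level functional profiles where one hydrogenase group
([FeFe] A3 analog) and eight animal-carbohydrate CAZy families follow a
shared gas-metabolism latent, aggregates genes to families, builds the
|rho| > 0.4 Spearman network, ranks hydrogenase groups by two-class LDA for
severe-vs-control, and recovers planted CAZotypes by mixture clustering.
"""

import numpy as np
import pandas as pd

from dietmg.function_analysis import (
    aggregate_families,
    cazotype_enterotype_assoc,
    cazotype_partition,
    correlation_network,
    lda_scores,
)
from dietmg.synthetic_data import gen_function_profiles

rng = np.random.default_rng(20)
ids = [f"s{i}" for i in range(100)]
enterotypes = pd.Series(rng.integers(1, 4, size=100), index=ids)
fx = gen_function_profiles(100, seed=21, sample_ids=ids, cazotype_labels=enterotypes)

cazy = aggregate_families(fx["gene_counts"], fx["cazy_map"], "CAZy")
hyd = aggregate_families(fx["gene_counts"], fx["hydrogenase_map"], "hydrogenase")

net = correlation_network(cazy, hyd, threshold=0.4)
print(f"network: {len(net.edges)} edges above |rho| = 0.4")
print(net.edges.sort_values('rho', ascending=False).head(8).to_string(index=False))

lda = lda_scores(hyd, fx["labels"])
top = lda.iloc[0]
print(
    f"top LDA feature for severe vs control: {top['feature']} "
    f"(score {top['score']:+.2f}; positive = enriched in severe)"
)

labels, fit = cazotype_partition(cazy, k_range=range(1, 5), seed=22)
chi2, df, p = cazotype_enterotype_assoc(labels, enterotypes)
print(f"CAZotypes: K = {fit.k}; association with enterotypes chi2 = {chi2:.1f} (p = {p:.2g})")
print(
    "-> the planted hydrogenase-glycan coupling, its severity enrichment and "
    "the enterotype-linked CAZotypes are all recovered from gene counts"
)
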