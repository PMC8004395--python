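"""Call MSP subspecies from accessory-gene presence patterns.

Plants two MSPs (one with 2, one with 3 subspecies as disjoint accessory
blocks) over 60 samples, runs the detection rule (median core coverage > 2),
the quantile-band presence calls, Jaccard + PAM clustering with silhouette
model selection, and compares the recovered partition with the planted one.
"""

from sklearn.metrics import adjusted_rand_score

from dietmg.msp_subspecies import (
    msp_core_abundance,
    subspecies_abundance,
    subspecies_partition_all,
)
from dietmg.synthetic_data import gen_msp_metagenome

counts, catalog, truth = gen_msp_metagenome(
    n_samples=60, n_msp=2, subspecies_spec=[[14, 14], [12, 12, 12]], seed=5
)
print(f"gene matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")

core_ab = msp_core_abundance(counts, catalog)
parts = subspecies_partition_all(counts, catalog, k_max=4, n_boot=50, seed=6)
for msp, part in parts.items():
    lab_true = truth.subspecies_labels[msp].loc[part.labels.index]
    ari = adjusted_rand_score(lab_true, part.labels)
    sil = part.silhouette.get(part.k, float("nan"))
    stab = min(part.stability.values())
    print(
        f"{msp}: k={part.k} (silhouette {sil:.2f}, min bootstrap stability "
        f"{stab:.2f}), ARI vs planted labels = {ari:.2f}"
    )

sub_ab = subspecies_abundance(parts, core_ab)
print(f"subspecies abundance table: {sub_ab.shape[0]} subspecies rows")
print(
    "-> each detected sample's MSP abundance is attributed wholly to its "
    "assigned subspecies; ARI = 1 means the planted strains were recovered"
)
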