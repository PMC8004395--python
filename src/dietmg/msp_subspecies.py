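"""MSP subspecies delineation from gene counts.

A metagenomic species pangenome (MSP) is a co-abundant gene group split into
core genes (present in every carrier strain) and accessory genes.  Per
sample, an MSP is detected when its median core coverage exceeds 2; accessory
genes are called present when their coverage falls inside the 2.5-97.5%
quantile band of that sample's core coverages.  Samples are then clustered on
the Jaccard distance between accessory presence profiles with partition
around medoids (PAM); the cluster number is picked by mean silhouette width
and clusters are scored for stability by subset-bootstrap refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "MSPCatalog",
    "msp_core_abundance",
    "detect_msp",
    "accessory_presence",
    "accessory_matrix",
    "jaccard_distance",
    "pam",
    "partition_subspecies",
    "subspecies_partition_all",
    "subspecies_abundance",
    "gene_richness",
]

DETECTION_MEDIAN = 2.0
QUANTILE_BAND = (2.5, 97.5)


@dataclass
class MSPCatalog:
    """Mapping msp id -> core / accessory gene id sets, plus optional
    per-gene annotations (e.g. CAZy family, KO, hydrogenase group)."""

    members: dict
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        for msp, sets in self.members.items():
            core = set(sets["core"])
            acc = set(sets["accessory"])
            if not core:
                raise ValueError(f"{msp}: core gene set is empty")
            if core & acc:
                raise ValueError(f"{msp}: core and accessory genes overlap")

    @property
    def msp_ids(self):
        return list(self.members)

    def core(self, msp):
        return list(self.members[msp]["core"])

    def accessory(self, msp):
        return list(self.members[msp]["accessory"])


def msp_core_abundance(gene_counts: pd.DataFrame, catalog: MSPCatalog) -> pd.DataFrame:
    """MSP x sample abundance: per-sample median over the MSP's core genes.

    MSPs with no core gene present in the count matrix are omitted with a
    warning.
    """
    rows = {}
    for msp in catalog.msp_ids:
        core = [g for g in catalog.core(msp) if g in gene_counts.index]
        if not core:
            warnings.warn(f"{msp}: no core genes in the count matrix; omitted")
            continue
        rows[msp] = gene_counts.loc[core].median(axis=0)
    return pd.DataFrame(rows).T


def detect_msp(core_coverages) -> bool:
    """Detection rule: strictly more than ``DETECTION_MEDIAN`` median core
    coverage."""
    cov = np.asarray(core_coverages, dtype=float)
    if cov.size == 0:
        raise ValueError("need at least one core gene coverage")
    return bool(np.median(cov) > DETECTION_MEDIAN)


def accessory_presence(
    accessory_cov,
    core_cov,
    band=QUANTILE_BAND,
    multicopy="present",
):
    """Presence calls for one sample's accessory genes of one MSP.

    The call band is the ``band`` quantile interval of the sample's core
    coverages: inside -> present (1), below -> absent (0).  Coverage above
    the band flags a multi-copy/conserved gene; ``multicopy`` chooses whether
    those are coded ``"present"`` (default: the gene is evidently there) or
    ``"absent"``.  A degenerate band falls back to a coverage > 0 call with a
    warning.
    """
    acc = np.asarray(accessory_cov, dtype=float)
    core = np.asarray(core_cov, dtype=float)
    lo, hi = np.percentile(core, band)
    if lo == hi:
        warnings.warn("degenerate core-coverage quantile band; using >0 presence")
        return (acc > 0).astype(int)
    present = ((acc >= lo) & (acc <= hi)).astype(int)
    above = acc > hi
    if multicopy == "present":
        present[above] = 1
    elif multicopy == "absent":
        present[above] = 0
    else:
        raise ValueError("multicopy must be 'present' or 'absent'")
    return present


def accessory_matrix(
    gene_counts: pd.DataFrame,
    catalog: MSPCatalog,
    msp,
    band=QUANTILE_BAND,
    multicopy="present",
):
    """Binary samples x accessory-genes matrix for one MSP, restricted to the
    samples where the MSP is detected."""
    core = [g for g in catalog.core(msp) if g in gene_counts.index]
    acc = [g for g in catalog.accessory(msp) if g in gene_counts.index]
    if not core:
        raise ValueError(f"{msp}: no core genes in matrix")
    core_cov = gene_counts.loc[core]
    detected = [s for s in gene_counts.columns if detect_msp(core_cov[s])]
    rows = {
        s: accessory_presence(
            gene_counts.loc[acc, s], core_cov[s], band=band, multicopy=multicopy
        )
        for s in detected
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=acc)


def jaccard_distance(binary: pd.DataFrame):
    """Jaccard distance matrix between the rows of a binary matrix
    (1 - |intersection| / |union|; pairs of all-zero rows get 0 with a
    warning)."""
    if binary.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = np.asarray(binary, dtype=bool)
    if (~x.any(axis=1)).sum() >= 2:
        warnings.warn("pairs of all-empty profiles are assigned distance 0")
    inter = (x[:, None, :] & x[None, :, :]).sum(-1)
    union = (x[:, None, :] | x[None, :, :]).sum(-1)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=binary.index, columns=binary.index)


def pam(dist: np.ndarray, k: int, max_iter: int = 100):
    """Partition around medoids on a precomputed distance matrix.

    Deterministic greedy BUILD phase followed by the SWAP phase; returns
    (labels, medoid_indices).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n]")
    # BUILD: first medoid minimises total distance; then greedy gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dmin = d[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        cost = d[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = np.setdiff1d(np.arange(n), medoids)
            for h in others:
                trial = medoids.copy()
                trial[mi] = h
                delta = d[:, trial].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, medoids


def _cluster_jaccard(members_a, members_b):
    inter = len(members_a & members_b)
    union = len(members_a | members_b)
    return inter / union if union else 0.0


@dataclass
class SubspeciesPartition:
    """PAM partition of one MSP's detected samples."""

    labels: pd.Series  # sample -> cluster label (1..k)
    k: int
    silhouette: dict  # k -> mean silhouette width
    stability: dict  # cluster label -> mean bootstrap Jaccard
    medoids: list = field(default_factory=list)


def partition_subspecies(
    dist: pd.DataFrame,
    k_max: int = 4,
    n_boot: int = 100,
    subset_frac: float = 2 / 3,
    seed: int = 0,
    silhouette_floor: float = 0.25,
    stability_threshold: float = 0.6,
    boot_all_k: bool = False,
) -> SubspeciesPartition:
    """Cluster samples on a distance matrix into subspecies.

    PAM is fitted for k = 2..k_max on the full matrix; the k maximising the
    mean silhouette width is selected, unless that maximum is below
    ``silhouette_floor``, in which case no split is made (k = 1).  Cluster
    stability is the mean Jaccard agreement between each full-fit cluster and
    its best-matching cluster across ``n_boot`` refits on random
    ``subset_frac`` subsets drawn without replacement; clusters below
    ``stability_threshold`` are flagged by the caller.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    ids = list(dist.index)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, n - 1)
    rng = np.random.default_rng(seed)

    sil = {}
    fits = {}
    for k in range(2, k_max + 1):
        labels, medoids = pam(d, k)
        if len(np.unique(labels)) < 2:
            continue
        sil[k] = float(silhouette_score(d, labels, metric="precomputed"))
        fits[k] = (labels, medoids)
    if not sil or max(sil.values()) < silhouette_floor:
        return SubspeciesPartition(
            labels=pd.Series(1, index=ids), k=1, silhouette=sil, stability={1: 1.0}
        )
    best_k = max(sil, key=lambda k: (sil[k], -k))
    labels, medoids = fits[best_k]

    def boot_stability(k, full_labels):
        clusters = {
            lab: set(np.flatnonzero(full_labels == lab)) for lab in np.unique(full_labels)
        }
        agree = {lab: [] for lab in clusters}
        m = max(int(round(subset_frac * n)), k + 1)
        for _ in range(n_boot):
            idx = rng.choice(n, size=m, replace=False)
            sub_labels, _ = pam(d[np.ix_(idx, idx)], k)
            sub_clusters = [
                set(idx[np.flatnonzero(sub_labels == lab)])
                for lab in np.unique(sub_labels)
            ]
            for lab, members in clusters.items():
                inter = members & set(idx)
                if not inter:
                    continue
                agree[lab].append(
                    max(_cluster_jaccard(inter, sc) for sc in sub_clusters)
                )
        return {int(lab) + 1: float(np.mean(v)) if v else np.nan for lab, v in agree.items()}

    stability = {}
    for k in sorted(fits) if boot_all_k else [best_k]:
        st = boot_stability(k, fits[k][0])
        if k == best_k:
            stability = st
    return SubspeciesPartition(
        labels=pd.Series(labels + 1, index=ids),
        k=best_k,
        silhouette=sil,
        stability=stability,
        medoids=[ids[m] for m in medoids],
    )


def subspecies_partition_all(
    gene_counts: pd.DataFrame,
    catalog: MSPCatalog,
    k_max: int = 4,
    n_boot: int = 100,
    seed: int = 0,
    min_detected: int = 10,
    **kwargs,
) -> dict:
    """Run detection, presence calling and PAM clustering for every MSP with
    at least ``min_detected`` detected samples; returns msp ->
    SubspeciesPartition (k = 1 partitions for MSPs left unsplit)."""
    out = {}
    for i, msp in enumerate(catalog.msp_ids):
        binary = accessory_matrix(gene_counts, catalog, msp)
        if binary.shape[0] == 0:
            continue
        if binary.shape[0] < min_detected or binary.shape[1] == 0:
            out[msp] = SubspeciesPartition(
                labels=pd.Series(1, index=binary.index),
                k=1,
                silhouette={},
                stability={1: 1.0},
            )
            continue
        dist = jaccard_distance(binary)
        out[msp] = partition_subspecies(
            dist, k_max=k_max, n_boot=n_boot, seed=seed + i, **kwargs
        )
    return out


def subspecies_abundance(
    partitions: dict, core_abundance: pd.DataFrame
) -> pd.DataFrame:
    """Subspecies x sample abundance table.

    Each detected sample's MSP abundance is attributed wholly to its assigned
    subspecies; undetected samples get 0.  MSPs without a partition (or with
    k = 1) are carried as single unsplit units.
    """
    rows = {}
    for msp in core_abundance.index:
        ab = core_abundance.loc[msp]
        part = partitions.get(msp)
        if part is None:
            rows[f"{msp}_unassigned"] = ab
            continue
        for lab in sorted(part.labels.unique()):
            members = part.labels.index[part.labels == lab]
            vec = pd.Series(0.0, index=core_abundance.columns)
            vec.loc[members] = ab.loc[members]
            rows[f"{msp}_sub{lab}"] = vec
    return pd.DataFrame(rows).T


def gene_richness(gene_counts: pd.DataFrame, sample=None):
    """Number of genes with count > 0 (per sample, or for one sample)."""
    if sample is not None:
        return int((gene_counts[sample] > 0).sum())
    return (gene_counts > 0).sum(axis=0)
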