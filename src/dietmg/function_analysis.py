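"""CAZy-family and hydrogenase-group functional analysis.

Gene abundances are aggregated to carbohydrate-active enzyme (CAZy) families
or hydrogenase metal-site groups and renormalised per sample within each
annotation universe.  Samples are partitioned into CAZotypes with the same
Dirichlet multinomial mixture used for the food tree; CAZy-hydrogenase
couplings are screened with a Spearman correlation network (|rho| > 0.4 by
default) and two-class Fisher LDA ranks functional features by how strongly
they separate severe cases from controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dmm import DMMFit, fit_dmm

__all__ = [
    "aggregate_families",
    "cazotype_partition",
    "cazotype_enterotype_assoc",
    "CorrelationNetwork",
    "correlation_network",
    "lda_scores",
]


def aggregate_families(
    gene_counts: pd.DataFrame, annotation, universe: str = "families"
) -> pd.DataFrame:
    """Samples x families relative abundance within one annotation universe.

    ``annotation`` maps gene id -> family; unannotated genes are excluded and
    counts are renormalised per sample so rows sum to one.  A sample with no
    annotated counts raises an error naming it.
    """
    ann = pd.Series(annotation)
    genes = [g for g in gene_counts.index if g in ann.index]
    if not genes:
        raise ValueError("annotation covers no gene in the matrix")
    fam = ann.loc[genes]
    agg = gene_counts.loc[genes].groupby(fam).sum().T
    totals = agg.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise ValueError(f"samples with zero annotated counts in {universe}: {empty[:5]}")
    return agg.div(totals, axis=0)


def cazotype_partition(
    cazy_table: pd.DataFrame, k_range=(1, 2, 3, 4, 5), seed: int = 0, scale: float = 1e4
):
    """CAZotype labels by DMM clustering of CAZy relative abundances.

    Relative abundances are turned into pseudo-counts (x ``scale``, rounded)
    and fitted over ``k_range``; K comes from the minimum Laplace score.
    Returns ``(labels, fit)`` with labels 1..K indexed by sample.
    """
    counts = np.round(np.asarray(cazy_table, dtype=float) * scale).astype(int)
    fit: DMMFit = fit_dmm(counts, k_range, seed=seed)
    labels = pd.Series(fit.assignments + 1, index=cazy_table.index, name="cazotype")
    return labels, fit


def cazotype_enterotype_assoc(labels_a, labels_b):
    """Pearson chi-squared association between two sample partitions.

    Returns ``(chi2, df, p)`` from the uncorrected test on the contingency
    table; warns when any expected cell count drops below 1.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    common = a.index.intersection(b.index)
    if a.loc[common].nunique() < 2 or b.loc[common].nunique() < 2:
        raise ValueError("both partitions need at least 2 levels")
    table = pd.crosstab(a.loc[common], b.loc[common])
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-squared approximation is weak")
    return float(chi2), int(df), float(p)


@dataclass
class CorrelationNetwork:
    """Thresholded Spearman correlation network between functional families."""

    edges: pd.DataFrame  # family_a, family_b, rho, sign
    threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, e in self.edges.iterrows():
            g.add_edge(e["family_a"], e["family_b"], rho=e["rho"], sign=e["sign"])
        return g

    def write_edgelist(self, path):
        self.edges.to_csv(path, sep="\t", index=False)


def correlation_network(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    threshold: float = 0.4,
    include_within: bool = False,
) -> CorrelationNetwork:
    """Spearman correlation network between two family-abundance tables.

    Keeps every cross-table pair with |rho| strictly above ``threshold``
    (``include_within`` adds within-table pairs); constant columns are
    skipped with a warning.  Edge direction is meaningless; the sign of rho
    is retained.
    """
    common = table_a.index.intersection(table_b.index)
    if len(common) < 10:
        raise ValueError("need at least 10 common samples")
    a = table_a.loc[common]
    b = table_b.loc[common]
    for tbl, name in ((a, "first"), (b, "second")):
        const = [c for c in tbl.columns if tbl[c].nunique() == 1]
        if const:
            warnings.warn(f"constant columns skipped in {name} table: {const[:5]}")
    a = a.loc[:, a.nunique() > 1]
    b = b.loc[:, b.nunique() > 1]
    edges = []

    def scan(t1, t2, same):
        joint = np.column_stack([t1.to_numpy(), t2.to_numpy()])
        rho_mat = stats.spearmanr(joint).statistic
        if np.ndim(rho_mat) == 0:  # scipy collapses the 2-variable case
            rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        n1 = t1.shape[1]
        for i, fa in enumerate(t1.columns):
            js = range(i + 1, t2.shape[1]) if same else range(t2.shape[1])
            for j in js:
                fb = t2.columns[j]
                rho = rho_mat[i, n1 + j] if not same else rho_mat[i, j]
                if abs(rho) > threshold:
                    edges.append(
                        {
                            "family_a": fa,
                            "family_b": fb,
                            "rho": float(rho),
                            "sign": int(np.sign(rho)),
                        }
                    )

    scan(a, b, same=False)
    if include_within:
        rho_a = stats.spearmanr(a.to_numpy()).statistic
        rho_b = stats.spearmanr(b.to_numpy()).statistic
        for tbl, mat in ((a, rho_a), (b, rho_b)):
            mat = np.atleast_2d(mat)
            for i in range(tbl.shape[1]):
                for j in range(i + 1, tbl.shape[1]):
                    if abs(mat[i, j]) > threshold:
                        edges.append(
                            {
                                "family_a": tbl.columns[i],
                                "family_b": tbl.columns[j],
                                "rho": float(mat[i, j]),
                                "sign": int(np.sign(mat[i, j])),
                            }
                        )
    return CorrelationNetwork(
        edges=pd.DataFrame(edges, columns=["family_a", "family_b", "rho", "sign"]),
        threshold=threshold,
    )


def lda_scores(
    features: pd.DataFrame, labels, positive: str = "severe", ridge: float = 1e-8
) -> pd.DataFrame:
    """Per-feature discriminant scores from two-class Fisher LDA.

    Features are standardised (making scores invariant to rescaling), the
    pooled within-class covariance is inverted (ridge-regularised with a
    warning when singular) and the discriminant direction w = Sw^-1 (mu1 -
    mu0) is computed.  Each feature's score is |w| signed by its class-mean
    difference, so positive scores mark enrichment in the ``positive`` class;
    the table is ranked by score magnitude.
    """
    labels = pd.Series(labels)
    common = features.index.intersection(labels.index)
    y = labels.loc[common]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes}")
    if min((y == c).sum() for c in classes) < 5:
        raise ValueError("both classes need at least 5 samples")
    x = features.loc[common]
    x = (x - x.mean()) / x.std(ddof=1).replace(0, 1.0)
    neg = [c for c in classes if c != positive][0]
    x1 = x[y == positive].to_numpy()
    x0 = x[y == neg].to_numpy()
    mu1, mu0 = x1.mean(axis=0), x0.mean(axis=0)
    sw = np.cov(x1, rowvar=False) * (len(x1) - 1) + np.cov(x0, rowvar=False) * (
        len(x0) - 1
    )
    sw /= len(x1) + len(x0) - 2
    p = sw.shape[0]
    if np.linalg.cond(sw) > 1e10:
        warnings.warn("singular within-class scatter; ridge regularisation applied")
        sw = sw + 1e-3 * np.eye(p)
    else:
        sw = sw + ridge * np.eye(p)
    w = np.linalg.solve(sw, mu1 - mu0)
    diff_sign = np.sign(mu1 - mu0)
    score = np.abs(w) * np.where(diff_sign == 0, 1.0, diff_sign)
    out = pd.DataFrame(
        {
            "feature": x.columns,
            "loading": w,
            "mean_diff": mu1 - mu0,
            "score": score,
            "log10_magnitude": np.log10(1.0 + np.abs(score)),
        }
    ).sort_values("score", key=np.abs, ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
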