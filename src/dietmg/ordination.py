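"""Distance-based ordination and two-table coupling.

Provides sqrt Jensen-Shannon distances between metagenome compositions,
classical PCoA with out-of-sample (Gower) projection of new individuals,
PERMANOVA with continuous or categorical covariates (McArdle-Anderson trace
form) including a per-taxon-node scan over a taxonomy, co-inertia analysis of
paired PCoA coordinate blocks with the RV coefficient, projection of
single-block individuals through a fitted co-inertia model, and principal
component regression of clinical responses on co-inertia axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "jsd_distance",
    "PCoAResult",
    "pcoa",
    "pcoa_project",
    "PermanovaResult",
    "permanova",
    "permanova_scan",
    "CoInertiaModel",
    "coinertia",
    "project_single_block",
    "PCRegression",
    "pc_regression",
    "axis_feature_correlations",
]


def _as_dm(dist):
    if isinstance(dist, DistanceMatrix):
        return dist
    if isinstance(dist, pd.DataFrame):
        return DistanceMatrix(dist.to_numpy(), ids=[str(i) for i in dist.index])
    return DistanceMatrix(np.asarray(dist, dtype=float))


def jsd_distance(abundance: pd.DataFrame, pseudocount: float = 1e-6) -> DistanceMatrix:
    """sqrt Jensen-Shannon distance between samples (rows = samples).

    Zeros are replaced by ``pseudocount`` before normalising each sample to a
    probability vector; the returned value is the square root of the JSD in
    nats, a metric on the simplex.
    """
    x = np.asarray(abundance, dtype=float)
    if np.any(x.sum(axis=1) == 0):
        bad = list(np.asarray(abundance.index)[x.sum(axis=1) == 0][:5])
        raise ValueError(f"all-zero samples: {bad}")
    x = np.where(x == 0, pseudocount, x)
    p = x / x.sum(axis=1, keepdims=True)
    d = squareform(pdist(p, metric="jensenshannon"))
    return DistanceMatrix(d, ids=[str(i) for i in abundance.index])


@dataclass
class PCoAResult:
    """Classical (metric) MDS of a distance matrix.

    ``coords`` holds sample coordinates on the positive-eigenvalue axes,
    ordered by decreasing eigenvalue; ``proportion_explained`` uses positive
    eigenvalues only.  The centering statistics of the squared-distance
    matrix are retained so new samples can be projected from their distances
    to the training samples.
    """

    coords: pd.DataFrame
    eigvals: np.ndarray
    proportion_explained: np.ndarray
    ids: list
    _col_means: np.ndarray = field(repr=False, default=None)
    _grand_mean: float = field(repr=False, default=0.0)
    _vectors: np.ndarray = field(repr=False, default=None)


def pcoa(dist, n_axes: int | None = None) -> PCoAResult:
    """PCoA via eigendecomposition of the double-centered Gower matrix.

    Negative eigenvalues (from non-Euclidean distances) are dropped from both
    the axes and the variance fractions.
    """
    dm = _as_dm(dist)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    d2 = dm.data**2
    col_means = d2.mean(axis=0)
    grand = d2.mean()
    b = -0.5 * (d2 - col_means[None, :] - col_means[:, None] + grand)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10
    evals, evecs = evals[pos], evecs[:, pos]
    if n_axes is not None:
        evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    coords = evecs * np.sqrt(evals)[None, :]
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coords=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigvals=evals,
        proportion_explained=evals / evals.sum(),
        ids=list(dm.ids),
        _col_means=col_means,
        _grand_mean=grand,
        _vectors=evecs,
    )


def pcoa_project(result: PCoAResult, dist_to_train) -> pd.DataFrame:
    """Project new samples onto a fitted PCoA from their distances to the
    training samples (Gower's supplementary-point formula).

    ``dist_to_train`` is (new samples) x (training samples), column order
    matching ``result.ids``; projecting a training sample's own distance row
    reproduces its training coordinates exactly.
    """
    d = np.atleast_2d(np.asarray(dist_to_train, dtype=float))
    ids = None
    if isinstance(dist_to_train, pd.DataFrame):
        ids = list(dist_to_train.index)
        d = dist_to_train.reindex(columns=result.ids).to_numpy()
    if d.shape[1] != len(result.ids):
        raise ValueError("distance rows must cover all training samples")
    d2 = d**2
    b = -0.5 * (
        d2
        - d2.mean(axis=1, keepdims=True)
        - result._col_means[None, :]
        + result._grand_mean
    )
    coords = b @ result._vectors / np.sqrt(result.eigvals)[None, :]
    return pd.DataFrame(coords, index=ids, columns=result.coords.columns)


@dataclass
class PermanovaResult:
    r2: float
    f: float
    p: float
    n_perm: int


def _design(covariate, index=None):
    cov = pd.Series(covariate, index=index) if not isinstance(covariate, pd.Series) else covariate
    if cov.nunique() < 2:
        raise ValueError("covariate is constant")
    if cov.dtype.kind in "fiu":
        x = (cov - cov.mean()).to_numpy(float)[:, None]
    else:
        x = pd.get_dummies(cov, drop_first=True).to_numpy(float)
        x = x - x.mean(axis=0)
    return x


def permanova(dist, covariate, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA of a distance matrix on one covariate.

    Uses the McArdle-Anderson partition: with G the double-centered squared
    distance matrix and H the hat matrix of the (centered) covariate design,
    SS_among = tr(HG), R2 = SS_among / tr(G), pseudo-F the ratio of mean
    squares, and p the one-sided permutation tail (1 + #{F* >= F}) /
    (1 + n_perm).
    """
    dm = _as_dm(dist)
    n = dm.shape[0]
    x = _design(covariate, index=list(dm.ids))
    if x.shape[0] != n:
        raise ValueError("covariate length must match the distance matrix")
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_total = np.trace(g)
    df1 = np.linalg.matrix_rank(x)
    df2 = n - df1 - 1

    def f_stat(perm):
        hp = h[np.ix_(perm, perm)]
        ss_a = float(np.sum(hp * g.T))  # tr(H_perm G)
        ss_r = max(ss_total - ss_a, 0.0)
        if ss_r == 0.0:
            return ss_a, np.inf if ss_a > 0 else 0.0
        return ss_a, (ss_a / df1) / (ss_r / df2)

    ident = np.arange(n)
    ss_among, f_obs = f_stat(ident)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        _, f_p = f_stat(rng.permutation(n))
        if f_p >= f_obs - 1e-12:
            exceed += 1
    return PermanovaResult(
        r2=float(ss_among / ss_total),
        f=float(f_obs),
        p=(1 + exceed) / (1 + n_perm),
        n_perm=n_perm,
    )


def permanova_scan(
    dist,
    leaf_abundance: pd.DataFrame,
    taxonomy: pd.DataFrame,
    effect_threshold: float = 0.02,
    n_perm: int = 0,
    seed: int = 0,
):
    """Per-node PERMANOVA scan of a distance matrix over a taxonomy.

    ``leaf_abundance`` is samples x leaf taxa (e.g. subspecies); ``taxonomy``
    maps each leaf (index) to its lineage, one column per level from coarse
    to fine.  Node abundance is the sum of its member leaves; each node's
    abundance is used as a continuous PERMANOVA covariate against ``dist``.
    A lineage (leaf-to-root chain) is retained when any of its nodes has
    R2 > ``effect_threshold``; significance is deliberately not filtered.

    Returns ``(node_table, retained_leaves)``.
    """
    dm = _as_dm(dist)
    samples = list(dm.ids)
    ab = leaf_abundance.reindex(index=samples)
    levels = list(taxonomy.columns)
    node_rows = []
    node_r2 = {}
    for li, level in enumerate(levels):
        for node, leaves in taxonomy.groupby(level).groups.items():
            members = [l for l in leaves if l in ab.columns]
            if not members:
                continue
            vec = ab[members].sum(axis=1)
            if vec.nunique() < 2:
                continue
            if n_perm:
                res = permanova(dm, vec, n_perm=n_perm, seed=seed)
                r2, p = res.r2, res.p
            else:
                r2 = permanova(dm, vec, n_perm=0, seed=seed).r2
                p = np.nan
            node_rows.append(
                {"node": node, "level": level, "r2": r2, "p": p, "n_leaves": len(members)}
            )
            node_r2[node] = r2
    node_table = pd.DataFrame(node_rows)
    retained = []
    for leaf, row in taxonomy.iterrows():
        if any(node_r2.get(row[lv], 0.0) > effect_threshold for lv in levels):
            retained.append(leaf)
    return node_table, retained


@dataclass
class CoInertiaModel:
    """Co-inertia of two centered coordinate blocks over common samples.

    ``x_loadings`` / ``y_loadings`` are orthonormal (input axes x co-inertia
    axes); ``singular_values`` are the nonincreasing covariation singular
    values; ``rv`` is the RV matrix-correlation coefficient in [0, 1];
    row scores are the centered blocks projected on their loadings.
    """

    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    singular_values: np.ndarray
    rv: float
    n_axes: int
    x_mean: pd.Series
    y_mean: pd.Series
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    ids: list


def _rv_coefficient(xc, yc):
    wx = xc @ xc.T
    wy = yc @ yc.T
    return float(
        np.sum(wx * wy) / np.sqrt(np.sum(wx * wx) * np.sum(wy * wy))
    )


def coinertia(x_coords: pd.DataFrame, y_coords: pd.DataFrame, n_axes: int = 7) -> CoInertiaModel:
    """Fit co-inertia on the common samples of two PCoA coordinate blocks.

    The cross-covariance of the column-centered blocks (uniform row weights)
    is decomposed by SVD; co-inertia axes are the projections on the paired
    singular vectors and RV measures the overall covariation.
    """
    common = [i for i in x_coords.index if i in set(y_coords.index)]
    if len(common) < 3:
        raise ValueError("need at least 3 common samples")
    x = x_coords.loc[common]
    y = y_coords.loc[common]
    x_mean, y_mean = x.mean(), y.mean()
    xc = (x - x_mean).to_numpy()
    yc = (y - y_mean).to_numpy()
    cross = xc.T @ yc / len(common)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    n_axes = min(n_axes, len(s))
    u, s, v = u[:, :n_axes], s[:n_axes], vt.T[:, :n_axes]
    axes = [f"A{i + 1}" for i in range(n_axes)]
    return CoInertiaModel(
        x_loadings=pd.DataFrame(u, index=x.columns, columns=axes),
        y_loadings=pd.DataFrame(v, index=y.columns, columns=axes),
        singular_values=s,
        rv=_rv_coefficient(xc, yc),
        n_axes=n_axes,
        x_mean=x_mean,
        y_mean=y_mean,
        x_scores=pd.DataFrame(xc @ u, index=common, columns=axes),
        y_scores=pd.DataFrame(yc @ v, index=common, columns=axes),
        ids=common,
    )


def project_single_block(model: CoInertiaModel, coords: pd.DataFrame, block: str) -> pd.DataFrame:
    """Co-inertia coordinates of individuals with only one data block.

    ``coords`` must be expressed on the same PCoA axes the model was trained
    on (project new individuals with :func:`pcoa_project` first); ``block``
    selects the diet or microbiome side ('x'/'diet' or 'y'/'microbiome').
    """
    if block in ("x", "diet"):
        loadings, mean = model.x_loadings, model.x_mean
    elif block in ("y", "microbiome", "mgs"):
        loadings, mean = model.y_loadings, model.y_mean
    else:
        raise ValueError("block must be 'diet' or 'microbiome'")
    if list(coords.columns) != list(loadings.index):
        raise ValueError("coordinate axes do not match the trained block axes")
    centered = coords - mean
    return pd.DataFrame(
        centered.to_numpy() @ loadings.to_numpy(),
        index=coords.index,
        columns=loadings.columns,
    )


@dataclass
class PCRegression:
    """OLS of a response on the first k co-inertia axes."""

    response: str
    k: int
    intercept: float
    coef: np.ndarray
    train_r: float
    train_p: float
    axes: list

    def predict(self, coords: pd.DataFrame) -> pd.Series:
        x = coords[self.axes].to_numpy()
        return pd.Series(self.intercept + x @ self.coef, index=coords.index)

    def score(self, coords: pd.DataFrame, y) -> tuple:
        """Pearson r (and two-sided p) between predictions and observations."""
        yhat = self.predict(coords)
        y = pd.Series(y).loc[yhat.index]
        r, p = stats.pearsonr(yhat.to_numpy(), y.to_numpy(float))
        return float(r), float(p)


def pc_regression(train_coords: pd.DataFrame, y, k: int = 5, response: str = "y") -> PCRegression:
    """Fit OLS on the first ``k`` axes of the training coordinates."""
    if k > train_coords.shape[1]:
        raise ValueError("k exceeds the number of available axes")
    if k >= len(train_coords):
        raise ValueError("k must be smaller than the training size")
    axes = list(train_coords.columns[:k])
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=train_coords.index)
    y = y.loc[train_coords.index].to_numpy(float)
    x = np.column_stack([np.ones(len(y)), train_coords[axes].to_numpy()])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ beta
    if np.std(yhat) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(yhat, y)
    return PCRegression(
        response=response,
        k=k,
        intercept=float(beta[0]),
        coef=beta[1:],
        train_r=float(r),
        train_p=float(p),
        axes=axes,
    )


def axis_feature_correlations(
    features: pd.DataFrame, axes: pd.DataFrame, bh_adjust: bool = True
) -> pd.DataFrame:
    """Spearman correlation of each feature with each ordination axis.

    Returns a tidy table (feature, axis, rho, p, q) with Benjamini-Hochberg
    adjusted q-values over all computed tests; constant features yield
    missing rho/p and are excluded from the adjustment.
    """
    common = [i for i in features.index if i in set(axes.index)]
    f = features.loc[common]
    a = axes.loc[common]
    rows = []
    for feat in f.columns:
        fv = f[feat].to_numpy(float)
        for ax in a.columns:
            if np.nanstd(fv) == 0:
                rows.append({"feature": feat, "axis": ax, "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(fv, a[ax].to_numpy(), nan_policy="omit")
            rows.append({"feature": feat, "axis": ax, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    if bh_adjust and out["p"].notna().any():
        mask = out["p"].notna()
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
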