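"""sqrt-JSD, PCoA with projection, PERMANOVA, co-inertia and regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from dietmg.ordination import (
    axis_feature_correlations,
    coinertia,
    jsd_distance,
    pc_regression,
    pcoa,
    pcoa_project,
    permanova,
    permanova_scan,
    project_single_block,
)


def euclid(x):
    return squareform(pdist(x))


class TestJSD:
    def test_identity_and_disjoint_closed_form(self):
        t = pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
            index=["a", "b", "c", "d"],
        )
        dm = jsd_distance(t, pseudocount=1e-9)
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-6)
        # disjoint one-hot compositions: sqrt(ln 2) in nats
        assert dm["c", "d"] == pytest.approx(np.sqrt(np.log(2)), abs=1e-3)

    def test_metric_on_random_compositions(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.dirichlet(np.ones(12) * 0.5, size=30))
        d = jsd_distance(t).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = d.shape[0]
        for i in range(n):
            # vectorised exhaustive triangle check for vertex i
            assert np.all(d[i, None, :] <= d[i, :, None] + d + 1e-12)

    def test_all_zero_sample_raises(self):
        t = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            jsd_distance(t)


class TestPCoA:
    def test_points_on_a_line_load_one_axis(self):
        x = np.arange(6, dtype=float)[:, None]
        res = pcoa(euclid(x))
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_reconstructs_planar_configuration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 2))
        res = pcoa(euclid(x))
        got = res.coords.to_numpy()[:, :2]
        # Procrustes: distances must be reproduced exactly
        assert np.allclose(euclid(got), euclid(x), atol=1e-8)

    def test_matches_scikit_bio(self):
        rng = np.random.default_rng(1)
        d = euclid(rng.normal(size=(12, 4)))
        mine = pcoa(d)
        from skbio.stats.ordination import pcoa as sk_pcoa

        ref = sk_pcoa(d, number_of_dimensions=3)
        for k in range(3):
            a = mine.coords.to_numpy()[:, k]
            b = ref.samples.to_numpy()[:, k]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            pcoa(np.zeros((2, 2)))

    def test_projection_reproduces_training_coordinates(self):
        rng = np.random.default_rng(2)
        d = euclid(rng.normal(size=(20, 5)))
        res = pcoa(d)
        proj = pcoa_project(res, d[3:6, :])
        assert np.allclose(proj.to_numpy(), res.coords.iloc[3:6].to_numpy(), atol=1e-10)

    def test_out_of_sample_projection_recovers_held_out_geometry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 3))
        d_all = euclid(x)
        res = pcoa(d_all[:20][:, :20])
        proj = pcoa_project(res, d_all[20:, :20])
        # distances between projected held-out points approximate the truth
        got = euclid(proj.to_numpy()[:, :3])
        want = euclid(x[20:])
        assert pearsonr(squareform(got), squareform(want))[0] > 0.99


class TestPermanova:
    def test_degenerate_two_cluster_construction(self):
        n = 20
        d = np.ones((n, n))
        d[:10, :10] = 0
        d[10:, 10:] = 0
        np.fill_diagonal(d, 0)
        g = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(d, g, n_perm=199, seed=1)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.p == pytest.approx(1 / 200)

    def test_matches_scikit_bio_pseudo_f(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(24, 3))
        x[:12] += 1.0
        d = euclid(x)
        g = ["a"] * 12 + ["b"] * 12
        mine = permanova(d, np.array(g), n_perm=99, seed=0)
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        ref = sk_permanova(DistanceMatrix(d), grouping=g, permutations=99)
        assert mine.f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_duplicated_dataset_preserves_r2(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 3))
        g = rng.normal(size=15)
        r1 = permanova(euclid(x), g, n_perm=0).r2
        x2 = np.vstack([x, x])
        r2 = permanova(euclid(x2), np.concatenate([g, g]), n_perm=0).r2
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError):
            permanova(euclid(np.random.default_rng(0).normal(size=(10, 2))), np.ones(10))


class TestPermanovaScan:
    def _setup(self, coupled):
        rng = np.random.default_rng(7)
        n = 40
        grad = rng.normal(size=n)
        d = euclid(grad[:, None])
        samples = [f"s{i}" for i in range(n)]
        # the two sp1 subspecies replace each other along the gradient, so
        # their sum (the species node) carries a diluted signal
        ab = pd.DataFrame(
            {
                "sp1_sub1": np.exp((1.5 * grad if coupled else rng.normal(size=n)) + rng.normal(0, 0.3, n)),
                "sp1_sub2": np.exp((-1.5 * grad if coupled else rng.normal(size=n)) + rng.normal(0, 0.3, n)),
                "sp2_sub1": np.exp(rng.normal(0, 0.5, size=n)),
            },
            index=samples,
        )
        taxonomy = pd.DataFrame(
            {
                "phylum": ["P1", "P1", "P1"],
                "species": ["sp1", "sp1", "sp2"],
                "subspecies": ["sp1_sub1", "sp1_sub2", "sp2_sub1"],
            },
            index=["sp1_sub1", "sp1_sub2", "sp2_sub1"],
        )
        dm = pd.DataFrame(d, index=samples, columns=samples)
        return dm, ab, taxonomy

    def test_coupled_subspecies_node_beats_its_parent(self):
        dm, ab, tax = self._setup(coupled=True)
        table, retained = permanova_scan(dm, ab, tax)
        r2 = table.set_index("node")["r2"]
        assert r2["sp1_sub1"] > r2["sp1"]
        assert r2["sp1_sub1"] > 0.02
        assert "sp1_sub1" in retained

    def test_null_abundance_sits_near_baseline(self):
        dm, ab, tax = self._setup(coupled=False)
        table, _ = permanova_scan(dm, ab, tax)
        # baseline R2 for one continuous covariate is ~1/(n-1)
        assert (table["r2"] < 0.15).all()


class TestCoinertia:
    def _blocks(self, n=100, p=6, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        x = pd.DataFrame(rng.normal(size=(n, p)), index=idx)
        y = pd.DataFrame(rng.normal(size=(n, p)), index=idx)
        return x, y

    def test_duplicated_block_gives_rv_one(self):
        x, _ = self._blocks()
        m = coinertia(x, x.copy(), n_axes=4)
        assert m.rv == pytest.approx(1.0, abs=1e-10)

    def test_independent_blocks_give_small_rv(self):
        x, y = self._blocks(seed=11)
        assert coinertia(x, y, n_axes=4).rv < 0.2

    def test_rv_invariant_to_rotation(self):
        x, y = self._blocks(n=40, seed=2)
        y = x + 0.5 * y  # correlated blocks
        rv0 = coinertia(x, y).rv
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(x.shape[1],) * 2))
        y_rot = pd.DataFrame(y.to_numpy() @ q, index=y.index)
        assert coinertia(x, y_rot).rv == pytest.approx(rv0, abs=1e-10)

    def test_loadings_orthonormal_and_singular_values_sorted(self):
        x, y = self._blocks(n=50, seed=4)
        m = coinertia(x, (x + y) / 2, n_axes=5)
        u = m.x_loadings.to_numpy()
        assert np.allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-10)
        assert np.all(np.diff(m.singular_values) <= 1e-12)

    def test_projection_consistency_and_errors(self):
        x, y = self._blocks(n=30, seed=5)
        m = coinertia(x, y, n_axes=3)
        back = project_single_block(m, x, "diet")
        assert np.allclose(back.to_numpy(), m.x_scores.to_numpy(), atol=1e-10)
        # the block mean projects to the origin
        mean_row = pd.DataFrame([m.x_mean], index=["mean"])
        assert np.allclose(project_single_block(m, mean_row, "diet").to_numpy(), 0.0)
        with pytest.raises(ValueError):
            project_single_block(m, x.iloc[:, :2], "diet")

    def test_too_few_common_samples_raise(self):
        x, y = self._blocks(n=4)
        with pytest.raises(ValueError):
            coinertia(x.iloc[:2], y)


class TestPCRegression:
    def test_noise_free_linear_response_is_reproduced(self):
        rng = np.random.default_rng(6)
        coords = pd.DataFrame(
            rng.normal(size=(30, 5)), columns=[f"A{i+1}" for i in range(5)],
            index=[f"s{i}" for i in range(30)],
        )
        y = 2.0 + 3.0 * coords["A1"]
        reg = pc_regression(coords.iloc[:20], y.iloc[:20], k=5)
        r, p = reg.score(coords.iloc[20:], y)
        assert r == pytest.approx(1.0)
        assert reg.train_r == pytest.approx(1.0)

    def test_permuted_response_is_not_predictable(self):
        rng = np.random.default_rng(7)
        small = 0
        for rep in range(50):
            coords = pd.DataFrame(
                rng.normal(size=(60, 5)), index=[f"s{i}" for i in range(60)]
            )
            y = pd.Series(rng.permutation(np.arange(60, dtype=float)), index=coords.index)
            reg = pc_regression(coords.iloc[:40], y.iloc[:40], k=5)
            r, p = reg.score(coords.iloc[40:], y)
            small += p > 0.05
        assert small >= 40  # >=80% of null replicates non-significant

    def test_k_validation(self):
        coords = pd.DataFrame(np.eye(4), columns=list("abcd"))
        with pytest.raises(ValueError):
            pc_regression(coords, np.arange(4.0), k=5)
        with pytest.raises(ValueError):
            pc_regression(coords, np.arange(4.0), k=4)


class TestAxisCorrelations:
    def test_feature_equal_to_axis_and_bh(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(50)]
        axes = pd.DataFrame({"A1": rng.normal(size=50)}, index=idx)
        feats = pd.DataFrame(
            {"same": axes["A1"], "noise": rng.normal(size=50), "const": 1.0},
            index=idx,
        )
        out = axis_feature_correlations(feats, axes)
        same = out[out.feature == "same"].iloc[0]
        assert same["rho"] == pytest.approx(1.0)
        assert np.isnan(out[out.feature == "const"].iloc[0]["rho"])

    def test_bh_adjustment_hand_case(self):
        from statsmodels.stats.multitest import multipletests

        pvals = [0.01, 0.02, 0.04, 0.8]
        q = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.04 + 0.04 / 3, 0.8])
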