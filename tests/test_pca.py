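import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meapipe.pca import (
    PRESETS,
    ParameterVectorSpec,
    build_vectors,
    cluster_separation,
    feature_pc1_projection,
    pca_fit,
    standardize_by_timepoint,
)


class TestBuildVectors:
    def test_log10_transform(self):
        df = pd.DataFrame({"well": ["A1"], "wmfr_hz": [10.0], "wtmfr_hz": [1.0],
                           "mean_isi_s": [0.1], "n_active_electrodes": [16]})
        vec = build_vectors(df, PRESETS["spiking_4"])
        assert vec.loc["A1", "wmfr_hz"] == pytest.approx(1.0)
        assert vec.loc["A1", "mean_isi_s"] == pytest.approx(-1.0)

    def test_nonpositive_under_log_becomes_missing(self):
        df = pd.DataFrame({"well": ["A1", "A2"], "wmbr_hz": [0.0, 1.0],
                           "mean_burst_duration_s": [0.2, 0.2],
                           "mean_spikes_per_burst": [6, 6]})
        vec = build_vectors(df, PRESETS["bursting_3"])
        assert np.isnan(vec.loc["A1", "wmbr_hz"])
        assert vec.dropna().index.tolist() == ["A2"]

    def test_preset_column_order_as_stated(self):
        assert PRESETS["spiking_4"].columns == [
            "n_active_electrodes", "wmfr_hz", "wtmfr_hz", "mean_isi_s"
        ]
        assert len(PRESETS["bursting_3"].columns) == 3
        assert len(PRESETS["network_4"].columns) == 4
        assert len(PRESETS["full_19"].columns) == 19

    def test_unknown_parameter_is_config_error(self):
        spec = ParameterVectorSpec("bad", (("nonexistent", "identity"),))
        with pytest.raises(KeyError, match="nonexistent"):
            build_vectors(pd.DataFrame({"well": ["A1"], "x": [1.0]}), spec)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ParameterVectorSpec("dup", (("a", "identity"), ("a", "log10")))


class TestStandardize:
    def test_column_z_scored_with_sample_sd(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, dropped = standardize_by_timepoint(df)
        np.testing.assert_allclose(z["x"], [-1, 0, 1])
        assert dropped == []

    def test_already_standard_column_unchanged(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        z, _ = standardize_by_timepoint(pd.DataFrame({"x": x}))
        np.testing.assert_allclose(z["x"], x, atol=1e-12)

    def test_single_timepoint_equals_global(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        z1, _ = standardize_by_timepoint(df)
        z2, _ = standardize_by_timepoint(df, timepoint=pd.Series(["t0"] * 20, index=df.index))
        np.testing.assert_allclose(z1, z2)

    def test_per_timepoint_centering(self, rng):
        df = pd.DataFrame({"x": np.r_[rng.normal(0, 1, 10), rng.normal(100, 1, 10)]})
        tp = pd.Series(["t0"] * 10 + ["t1"] * 10, index=df.index)
        z, _ = standardize_by_timepoint(df, timepoint=tp)
        assert abs(z["x"][:10].mean()) < 1e-12
        assert abs(z["x"][10:].mean()) < 1e-12

    def test_zero_variance_column_dropped_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z, dropped = standardize_by_timepoint(df)
        assert dropped == ["c"]
        assert list(z.columns) == ["x"]


class TestPCAFit:
    def test_collinear_data_put_all_variance_on_pc1(self, rng):
        t = rng.normal(size=40)
        df = pd.DataFrame({"a": t, "b": 2 * t})
        res = pca_fit(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_data_split_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        res = pca_fit(df)
        assert res.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_reconstruction_from_scores_and_loadings(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        df.columns = [f"p{i}" for i in range(5)]
        res = pca_fit(df)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean_
        np.testing.assert_allclose(recon, df.to_numpy(), atol=1e-10)

    def test_explained_fractions_sorted_and_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)) * np.arange(1, 7))
        evr = pca_fit(df).explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        l1 = pca_fit(df).loadings
        l2 = pca_fit(df * 1.0).loadings
        np.testing.assert_allclose(l1, l2)
        for col in l1.columns:
            assert l1[col].iloc[np.argmax(np.abs(l1[col].to_numpy()))] > 0

    def test_missing_values_direct_to_completeness_filter(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="completeness"):
            pca_fit(df)


class TestClusterSeparation:
    def _fixed_cov_groups(self, offset):
        c = np.sqrt(1.5)
        base = np.array([[c, 0], [-c, 0], [0, c], [0, -c]])
        a = base + np.asarray(offset)
        b = base.copy()
        return np.vstack([a, b]), np.array(["a"] * 4 + ["b"] * 4)

    def test_identical_centroids_give_zero(self):
        X, lab = self._fixed_cov_groups([0.0, 0.0])
        sep = cluster_separation(X, lab)
        assert sep.mahalanobis_d == pytest.approx(0.0, abs=1e-12)
        assert sep.f_value == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_case_with_identity_pooled_covariance(self):
        X, lab = self._fixed_cov_groups([3.0, 4.0])
        sep = cluster_separation(X, lab)
        assert sep.mahalanobis_d == pytest.approx(5.0, abs=1e-10)

    def test_hotelling_closed_form(self):
        # n_a = n_b = 10, D^2 = 25 -> T^2 = 125, F = 17/36 * 125
        rng = np.random.default_rng(3)
        # 10 zero-mean points per group with sample covariance exactly I
        c = np.sqrt(4.5)
        base = np.vstack([np.eye(2) * c, -np.eye(2) * c, np.zeros((6, 2))])
        shift = rng.normal(size=2)
        X = np.vstack([base + shift + np.array([3.0, 4.0]), base + shift])
        lab = np.array(["a"] * 10 + ["b"] * 10)
        sep = cluster_separation(X, lab)
        assert sep.hotelling_t2 == pytest.approx(125.0, abs=1e-9)
        assert sep.f_value == pytest.approx(17 / 36 * 125, abs=1e-9)
        assert sep.dof == (2, 17)

    def test_matches_reference_hotelling_implementation(self, rng):
        import pingouin

        for _ in range(20):
            a = rng.normal(size=(12, 2))
            b = rng.normal(loc=0.5, size=(15, 2))
            X = np.vstack([a, b])
            lab = np.array(["a"] * 12 + ["b"] * 15)
            sep = cluster_separation(X, lab)
            ref = pingouin.multivariate_ttest(a, b)
            assert sep.hotelling_t2 == pytest.approx(float(ref["T2"].iloc[0]), abs=1e-8)
            assert sep.f_value == pytest.approx(float(ref["F"].iloc[0]), abs=1e-8)
            assert sep.p_value == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-8)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=(15, 2))
        b = rng.normal(loc=1.0, size=(15, 2))
        X = np.vstack([a, b])
        lab = np.array(["a"] * 15 + ["b"] * 15)
        d0 = cluster_separation(X, lab).mahalanobis_d
        for _ in range(10):
            M = rng.normal(size=(2, 2))
            while abs(np.linalg.det(M)) < 0.1:
                M = rng.normal(size=(2, 2))
            shift = rng.normal(size=2)
            d1 = cluster_separation(X @ M + shift, lab).mahalanobis_d
            assert d1 == pytest.approx(d0, abs=1e-8)

    def test_null_exceedance_calibrated(self, rng):
        crit = sps.f.ppf(0.95, 2, 17)
        exceed = 0
        n_rep = 2000
        for _ in range(n_rep):
            X = rng.normal(size=(20, 2))
            lab = np.array(["a"] * 10 + ["b"] * 10)
            if cluster_separation(X, lab).f_value > crit:
                exceed += 1
        assert exceed / n_rep == pytest.approx(0.05, abs=0.02)

    def test_too_small_groups_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError, match="p\\+1"):
            cluster_separation(X, ["a", "a", "b", "b"])

    def test_singular_covariance_suggests_ridge(self):
        X = np.zeros((8, 2))
        X[:4, 0] = [1, 2, 3, 4]
        X[4:, 0] = [5, 6, 7, 8]
        lab = ["a"] * 4 + ["b"] * 4
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            cluster_separation(X, lab)
        sep = cluster_separation(X, lab, ridge=1e-6)
        assert np.isfinite(sep.f_value)


class TestFeaturePC1:
    def _metrics_table(self, rng, factor_a=1.0):
        rows = []
        for cohort in ("c1", "c2"):
            for i in range(12):
                f = factor_a if i < 6 else 1.0
                rows.append({
                    "well": f"W{i}", "cohort": cohort,
                    "n_active_electrodes": 16,
                    "wmfr_hz": f * rng.lognormal(0, 0.2),
                    "wtmfr_hz": f * rng.lognormal(0, 0.2),
                    "mean_isi_s": rng.lognormal(-1, 0.2) / f,
                })
        return pd.DataFrame(rows)

    def test_scores_centered_per_cohort(self, rng):
        proj = feature_pc1_projection(self._metrics_table(rng), "spiking_4")
        for _, grp in proj.groupby("cohort"):
            assert abs(grp["pc1"].mean()) < 1e-10

    def test_higher_activity_maps_to_positive_pc1(self, rng):
        proj = feature_pc1_projection(self._metrics_table(rng, factor_a=3.0), "spiking_4")
        hot = proj[proj["well"].isin([f"W{i}" for i in range(6)])]["pc1"].mean()
        cold = proj[~proj["well"].isin([f"W{i}" for i in range(6)])]["pc1"].mean()
        assert hot > cold

    def test_small_cohort_skipped_with_warning(self, rng):
        tab = self._metrics_table(rng).iloc[:2]
        with pytest.warns(UserWarning, match="skipped"):
            proj = feature_pc1_projection(tab, "spiking_4")
        assert proj.empty
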