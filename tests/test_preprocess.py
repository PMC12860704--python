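import numpy as np
import pandas as pd
import pytest

from lipidstat.annotation import annotate_panel
from lipidstat.core import ContractError, StageError
from lipidstat.preprocess import (
    EpsPolicy,
    PreprocessConfig,
    class_sum_normalize,
    filter_by_missingness,
    knn_impute,
    logit_transform,
    run_preprocessing,
    zscore,
)

from conftest import make_matrix


def brute_force_knn_impute(values: np.ndarray, k: int) -> np.ndarray:
    """Independent enumeration oracle for feature-space KNN imputation.

    Standardizes each feature over its observed cells, enumerates every
    feature pair's pairwise-complete Euclidean distance (root mean squared
    difference over co-observed samples), and fills each missing cell with
    the donor-average standardized value mapped back to the target scale.
    """
    values = np.array(values, dtype=float)
    n, s = values.shape
    mu = np.array([np.nanmean(values[i]) for i in range(n)])
    sd = np.array([np.nanstd(values[i], ddof=1) for i in range(n)])
    sd[(sd == 0) | ~np.isfinite(sd)] = 1.0
    z = (values - mu[:, None]) / sd[:, None]
    out = values.copy()
    for i in range(n):
        for j in range(s):
            if not np.isnan(values[i, j]):
                continue
            dists = []
            for other in range(n):
                if other == i or np.isnan(values[other, j]):
                    continue
                common = ~np.isnan(z[i]) & ~np.isnan(z[other])
                if common.sum() == 0:
                    continue
                d = np.sqrt(np.mean((z[i, common] - z[other, common]) ** 2))
                dists.append((d, other))
            if not dists:
                out[i, j] = np.nanmedian(values[i])
                continue
            dists.sort(key=lambda t: t[0])
            donors = [o for _, o in dists[:k]]
            out[i, j] = mu[i] + sd[i] * np.mean([z[o, j] for o in donors])
    return out


class TestMissingnessFilter:
    def test_boundary_is_strict(self):
        """Exactly half missing is dropped; anything below is retained."""
        vals = np.ones((3, 10))
        vals[0, :6] = np.nan  # 6/10 missing
        vals[1, :5] = np.nan  # exactly 5/10
        vals[2, :4] = np.nan  # 4/10
        m = make_matrix(vals)
        kept, report = filter_by_missingness(m, 0.5)
        assert kept.n_features == 1
        assert set(report.index) == set(m.feature_names[:2])

    def test_complete_feature_retained_unchanged(self):
        m = make_matrix(np.arange(8, dtype=float).reshape(2, 4))
        kept, report = filter_by_missingness(m)
        assert kept.data.equals(m.data)
        assert report.empty

    def test_threshold_domain(self):
        m = make_matrix(np.ones((2, 4)))
        with pytest.raises(ContractError):
            filter_by_missingness(m, 0.0)
        with pytest.raises(ContractError):
            filter_by_missingness(m, 1.5)


class TestKnnImpute:
    def test_complete_matrix_is_identity(self):
        m = make_matrix(np.arange(20, dtype=float).reshape(4, 5))
        out = knn_impute(m, k=2)
        assert out.data.equals(m.data)

    def test_duplicate_feature_is_nearest_donor(self):
        """With k=1 and an exact duplicate feature, imputation follows it.

        The donor's standardized value is mapped to the target's
        observed-cell location/scale, so the fill tracks the duplicate
        closely and ignores the off-scale distractor feature.
        """
        rng = np.random.default_rng(0)
        base = rng.normal(10.0, 2.0, size=8)
        vals = np.vstack([base, base, rng.normal(50.0, 9.0, size=8)])
        vals[0, 3] = np.nan
        m = make_matrix(vals)
        out = knn_impute(m, k=1)
        filled = out.data.iloc[0, 3]
        assert filled == pytest.approx(base[3], rel=0.02)
        # exact identity on the standardized scale of the target feature
        obs = np.delete(base, 3)
        z_donor = (base[3] - base.mean()) / base.std(ddof=1)
        expected = obs.mean() + obs.std(ddof=1) * z_donor
        assert filled == pytest.approx(expected, rel=1e-10)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(size=(8, 6))
        mask = rng.uniform(size=vals.shape) < 0.2
        vals[mask] = np.nan
        vals[:, 0] = rng.lognormal(size=8)  # keep one complete column
        m = make_matrix(vals)
        out = knn_impute(m, k=3)
        observed = ~np.isnan(vals)
        np.testing.assert_array_equal(
            out.data.to_numpy()[observed], vals[observed]
        )
        assert not out.data.isna().any().any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(10, 8)) * rng.lognormal(size=(10, 1))
        idx = rng.choice(80, size=5, replace=False)
        vals.flat[idx] = np.nan
        m = make_matrix(vals)
        out = knn_impute(m, k=3)
        expected = brute_force_knn_impute(vals, k=3)
        np.testing.assert_allclose(out.data.to_numpy(), expected, rtol=1e-10)

    def test_k_domain(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ContractError):
            knn_impute(m, k=0)
        with pytest.raises(ContractError):
            knn_impute(m, k=3)


class TestClassSumNormalize:
    def test_singleton_class_becomes_one(self):
        m = make_matrix([[5.0, 7.0]], feature_names=["MAG(18:0)"])
        out = class_sum_normalize(m, annotate_panel(m.feature_names))
        assert (out.data.to_numpy() == 1.0).all()
        assert out.stage == "class_fraction"

    def test_proportions(self):
        names = ["PC(30:0)", "PC(32:0)", "PC(34:0)"]
        m = make_matrix([[2.0, 2], [3, 3], [5, 5]], feature_names=names)
        out = class_sum_normalize(m, annotate_panel(names))
        np.testing.assert_allclose(out.data.iloc[:, 0], [0.2, 0.3, 0.5])

    def test_fractions_sum_to_one_per_class_on_random_input(self):
        rng = np.random.default_rng(3)
        names = [f"PC(3{i}:0)" for i in range(4)] + [f"FFA(1{i}:0)" for i in range(4)]
        m = make_matrix(rng.lognormal(size=(8, 5)), feature_names=names)
        ann = annotate_panel(names)
        out = class_sum_normalize(m, ann)
        for cls, idx in out.data.groupby(ann["class"]).groups.items():
            np.testing.assert_allclose(out.data.loc[idx].sum(axis=0), 1.0, atol=1e-9)
        assert ((out.data >= 0) & (out.data <= 1)).all().all()

    def test_scale_invariance(self):
        """Scaling a sample's class block leaves its fractions unchanged."""
        rng = np.random.default_rng(4)
        names = [f"PC(3{i}:0)" for i in range(5)]
        vals = rng.lognormal(size=(5, 4))
        ann = annotate_panel(names)
        a = class_sum_normalize(make_matrix(vals, feature_names=names), ann)
        scaled = vals.copy()
        scaled[:, 2] *= 37.5
        b = class_sum_normalize(make_matrix(scaled, feature_names=names), ann)
        np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy(), rtol=1e-12)

    def test_zero_class_sum_rejected(self):
        m = make_matrix([[0.0, 1.0]], feature_names=["MAG(18:0)"])
        with pytest.raises(ContractError, match="MAG"):
            class_sum_normalize(m, annotate_panel(m.feature_names))


class TestLogitAndZscore:
    def test_logit_values(self):
        m = make_matrix([[0.5, 0.2]], feature_names=["MAG(18:0)"],
                        stage="class_fraction")
        out = logit_transform(m, EpsPolicy(fixed=1e-6))
        assert out.data.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.data.iloc[0, 1] == pytest.approx(-1.3862943611, rel=1e-9)

    def test_logit_clamps_singleton_fraction(self):
        m = make_matrix([[1.0, 1.0], [0.3, 0.4]], stage="class_fraction")
        out = logit_transform(m, EpsPolicy(fixed=1e-4))
        assert np.isfinite(out.data.to_numpy()).all()
        assert out.data.iloc[0, 0] == pytest.approx(np.log((1 - 1e-4) / 1e-4))

    def test_zscore_two_sample_closed_form(self):
        """{a, b} with the n-1 SD maps to +-1/sqrt(2)."""
        m = make_matrix([[1.0, 3.0]], stage="logit")
        out = zscore(m)
        np.testing.assert_allclose(
            out.data.to_numpy()[0], [-0.70710678, +0.70710678], rtol=1e-8
        )

    def test_zscore_standardizes_and_drops_constant(self):
        vals = np.vstack([np.arange(6.0), np.full(6, 2.5)])
        m = make_matrix(vals, stage="logit")
        with pytest.warns(UserWarning, match="constant"):
            out = zscore(m)
        assert out.n_features == 1
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=1, ddof=1), 1.0, rtol=1e-12)


class TestChain:
    def test_stage_order_enforced(self):
        m = make_matrix(np.ones((2, 4)), stage="class_fraction")
        with pytest.raises(StageError):
            class_sum_normalize(m, annotate_panel(m.feature_names))
        z = make_matrix(np.ones((2, 4)), stage="zscore")
        with pytest.raises(StageError):
            logit_transform(z)

    def test_chain_equals_hand_composition(self):
        """No-missing input: run_preprocessing == composing the stages."""
        rng = np.random.default_rng(9)
        names = [f"PC(3{i}:0)" for i in range(4)] + [f"FFA(1{i}:1)" for i in range(4)]
        m = make_matrix(rng.lognormal(size=(8, 6)), feature_names=names)
        ann = annotate_panel(names)
        auto = run_preprocessing(m.copy(), PreprocessConfig())
        byhand = zscore(logit_transform(class_sum_normalize(m, ann)))
        np.testing.assert_allclose(
            auto.data.to_numpy(), byhand.data.to_numpy(), rtol=1e-12
        )
        assert auto.stage == "zscore"

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        names = [f"PC(3{i}:0)" for i in range(5)]
        vals = rng.lognormal(size=(5, 6))
        vals[0, 2] = np.nan
        a = run_preprocessing(make_matrix(vals, feature_names=names))
        b = run_preprocessing(make_matrix(vals, feature_names=names))
        assert a.data.equals(b.data)
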