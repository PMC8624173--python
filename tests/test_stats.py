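"""glog/EigenMS/autoscale/PCA and the nonparametric test chain."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarlipid.stats import (TransformedMatrix, autoscale, bh_adjust,
                              class_abundances, discriminant_species,
                              dunn_posthoc, eigenms_normalize, glog_transform,
                              kruskal_wallis, pca, run_statistics)


def _df(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr,
                        index=[f"sp{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


SIX_GROUPS = np.repeat(["CM", "DM", "DE", "E", "E+USB", "E+USP"], 5)


class TestGlog:
    def test_zero_maps_to_zero_at_lambda_two(self):
        out = glog_transform(_df([[0.0, 2.0]]), lam=2.0)
        assert out.data.iloc[0, 0] == pytest.approx(0.0)
        assert out.stages == ("glog",)

    def test_asymptotically_log2(self):
        lam = 0.5
        x = np.array([[100.0 * lam, 500.0, 1e4]])
        out = glog_transform(_df(x), lam=lam)
        assert np.allclose(out.data.values, np.log2(x), atol=0.01)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        if hi - lo < 1e-6 * (1.0 + hi):
            return   # below float resolution of the transform
        out = glog_transform(_df([[lo, hi]]), lam=1.0).data
        assert out.iloc[0, 0] < out.iloc[0, 1]

    def test_rejects_bad_lambda_and_negatives(self):
        with pytest.raises(ValueError, match="lambda"):
            glog_transform(_df([[1.0, 2.0]]), lam=0.0)
        with pytest.raises(ValueError, match="non-negative"):
            glog_transform(_df([[-1.0, 2.0]]))


class TestEigenMS:
    def _matrix_with_trend(self, batch_scale=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n_sp, n = 60, 30
        group_means = rng.normal(8.0, 1.0, size=(n_sp, 1)).repeat(n, axis=1)
        trend = np.sin(np.linspace(0, 3 * np.pi, n))
        trend -= trend.mean()
        loadings = rng.normal(0.0, 1.0, size=n_sp)
        noise = rng.normal(0.0, 0.2, size=(n_sp, n))
        x = group_means + batch_scale * np.outer(loadings, trend) + noise
        return _df(x), trend

    def test_zero_residual_variance_no_trends(self):
        x = np.tile(np.arange(6.0).repeat(5), (4, 1))  # exact group means
        t = TransformedMatrix(_df(x), stages=("glog",))
        out = eigenms_normalize(t, SIX_GROUPS, n_permutations=50, seed=1)
        assert np.allclose(out.data.values, x)

    def test_injected_trend_removed(self):
        df, trend = self._matrix_with_trend()
        t = TransformedMatrix(df, stages=("glog",))
        out = eigenms_normalize(t, SIX_GROUPS, n_permutations=200, seed=2)
        u = trend / np.linalg.norm(trend)

        def resid_var_along_trend(values):
            resid = values - pd.DataFrame(values).T.groupby(
                SIX_GROUPS).transform("mean").T.values
            return float(np.sum((resid @ u) ** 2))

        before = resid_var_along_trend(df.values)
        after = resid_var_along_trend(out.data.values)
        assert after <= 0.2 * before

    def test_group_means_preserved(self):
        df, _ = self._matrix_with_trend(seed=3)
        t = TransformedMatrix(df, stages=("glog",))
        out = eigenms_normalize(t, SIX_GROUPS, n_permutations=100, seed=4)
        for g in np.unique(SIX_GROUPS):
            idx = np.flatnonzero(SIX_GROUPS == g)
            assert np.allclose(df.values[:, idx].mean(axis=1),
                               out.data.values[:, idx].mean(axis=1),
                               atol=1e-8)

    def test_requires_replicated_groups(self):
        t = TransformedMatrix(_df([[1.0, 2.0]]), stages=("glog",))
        with pytest.raises(ValueError, match="2 groups"):
            eigenms_normalize(t, ["A", "B"])


class TestAutoscale:
    def test_row_mean_zero_sd_one(self):
        t = TransformedMatrix(_df([[1.0, 2.0, 3.0]]),
                              stages=("glog", "eigenms"))
        out = autoscale(t)
        row = out.data.iloc[0]
        assert abs(row.mean()) < 1e-10
        assert row.std(ddof=1) == pytest.approx(1.0)

    def test_constant_row_dropped_with_warning(self):
        t = TransformedMatrix(_df([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
                              stages=("glog", "eigenms"))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = autoscale(t)
        assert list(out.data.index) == ["sp0"]

    def test_single_sample_rejected(self):
        t = TransformedMatrix(_df([[1.0]]), stages=("glog", "eigenms"))
        with pytest.raises(ValueError, match="2 samples"):
            autoscale(t)


class TestPipelineOrder:
    def test_out_of_order_stage_rejected(self):
        raw = TransformedMatrix(_df([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="order"):
            autoscale(raw)
        with pytest.raises(ValueError, match="order"):
            eigenms_normalize(TransformedMatrix(_df([[1.0, 2.0]])),
                              ["A", "A"])

    def test_provenance_records_order(self, default_run):
        assert default_run["species_stats"]["transformed"].stages \
            == ("glog", "eigenms", "autoscale")


class TestPCA:
    def test_perfectly_correlated_pair(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        res = pca(_df(x))
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_sums_to_100(self):
        rng = np.random.default_rng(5)
        res = pca(_df(rng.normal(size=(20, 12))))
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(res.variance_explained) <= 1e-9).all()

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca(_df(np.ones((5, 4))))


class TestKruskalWallis:
    def test_identical_groups(self):
        assert kruskal_wallis([[1.0, 1.0], [1.0, 1.0]]) == (0.0, 1.0)

    def test_hand_computed_h(self):
        # ranks 1..9 in three blocks: H = 12/(9*10) * 3*5*( (2-5)^2 ... )/..
        h, p = kruskal_wallis([[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        assert h == pytest.approx(7.2, abs=1e-9)
        assert 0 < p < 0.05

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestDunn:
    def test_identical_pair(self):
        out = dunn_posthoc({"A": np.array([1.0, 2.0, 3.0]),
                            "B": np.array([1.0, 2.0, 3.0])})
        assert out["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_six_groups_fifteen_pairs(self):
        rng = np.random.default_rng(6)
        out = dunn_posthoc({g: rng.normal(size=5) for g in "ABCDEF"})
        assert len(out) == 15

    def test_antisymmetry(self):
        a, b = np.array([1.0, 2.0, 5.0]), np.array([3.0, 7.0, 9.0])
        zab = dunn_posthoc({"A": a, "B": b})["z"].iloc[0]
        zba = dunn_posthoc({"B": b, "A": a})["z"].iloc[0]
        assert zab == pytest.approx(-zba)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dunn_posthoc({"A": np.array([1.0]), "B": np.array([])})


class TestBH:
    def test_hand_stepup_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            for r, idx in enumerate(order):
                brute[idx] = min(1.0, min(p[order[j]] * m / (j + 1)
                                          for j in range(r, m)))
            assert np.allclose(bh_adjust(p), brute, atol=1e-12)

    def test_by_variant_is_more_conservative(self):
        p = [0.01, 0.04, 0.03, 0.20]
        assert (bh_adjust(p, method="by") >= bh_adjust(p, method="bh")).all()


class TestClassAggregation:
    def test_sum_and_conservation(self):
        data = _df([[1.0, 2.0], [2.5, 3.0], [4.0, 1.0]])
        mapping = {"sp0": "PG", "sp1": "PG", "sp2": "PI"}
        out = class_abundances(data, mapping)
        assert out.loc["PG"].tolist() == [3.5, 5.0]
        assert np.allclose(out.sum(axis=0), data.sum(axis=0))

    def test_unmapped_species_rejected(self):
        with pytest.raises(ValueError, match="without class"):
            class_abundances(_df([[1.0, 2.0]]), {})


class TestDiscriminants:
    def test_no_significant_species_empty(self, default_run):
        tests = default_run["species_stats"]["tests"]
        strict = tests.per_species.assign(q=1.0)
        from polarlipid.stats import TestResult
        res = discriminant_species(
            TestResult(per_species=strict, pairwise=tests.pairwise),
            default_run["species_stats"]["pca"])
        assert res.empty

    def test_top_n_exceeding_significant_set(self, default_run):
        tests = default_run["species_stats"]["tests"]
        n_sig = int((tests.per_species["q"] <= 0.05).sum())
        res = discriminant_species(tests, default_run["species_stats"]["pca"],
                                   top_n=10 * n_sig)
        assert len(res) == n_sig
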