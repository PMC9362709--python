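"""Scale preprocessing, PCA, double weighting and scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cati import (
    DataError,
    LoadingVector,
    WeightVector,
    compute_weights,
    pca_first_component,
    preprocess_scales,
    score_index,
    single_benchmark_loadings,
)
from cati.reference import (
    REFERENCE_TOP3_SHARE,
    REFERENCE_WEIGHTS,
    reference_coefficients,
    reference_loadings,
)
from cati.weighting import SCALES


def frame_from_matrix(mat):
    return pd.DataFrame(mat, columns=list(SCALES))


class TestPreprocess:
    def test_wave_averaging_matches_manual_loop(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({f"{s}_w{w}": rng.normal(size=50) for s in SCALES for w in (1, 2)})
        got = preprocess_scales(df)
        for s in SCALES:
            means = [(df.loc[i, f"{s}_w1"] + df.loc[i, f"{s}_w2"]) / 2 for i in df.index]
            means = np.array(means)
            expect = (means - means.mean()) / means.std(ddof=1)
            np.testing.assert_allclose(got[s].to_numpy(), expect, atol=1e-12)

    def test_single_wave_is_plain_zscore(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({f"{s}_w1": rng.normal(2, 3, 40) for s in SCALES})
        got = preprocess_scales(df)
        for s in SCALES:
            x = df[f"{s}_w1"].to_numpy()
            np.testing.assert_allclose(got[s], (x - x.mean()) / x.std(ddof=1), atol=1e-12)

    def test_columns_standardized(self, complete_cohort):
        got = preprocess_scales(complete_cohort)
        assert np.allclose(got.mean(), 0, atol=1e-9)
        assert np.allclose(got.std(ddof=1), 1, atol=1e-9)

    def test_zero_variance_scale_named(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({f"{s}_w1": rng.normal(size=30) for s in SCALES})
        df["wr_w1"] = 5.0
        with pytest.raises(DataError, match="wr"):
            preprocess_scales(df)

    def test_missing_wave_allowed_but_empty_respondent_rejected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({f"{s}_w{w}": rng.normal(size=30) for s in SCALES for w in (1, 2)})
        df.loc[0, "ls_w1"] = np.nan  # one wave missing: fine, average the other
        preprocess_scales(df)
        df.loc[0, "ls_w2"] = np.nan  # no wave left
        with pytest.raises(DataError, match="ls"):
            preprocess_scales(df)


def sample_correlated(rho_matrix, n, seed):
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(rho_matrix)
    return frame_from_matrix(rng.standard_normal((n, 5)) @ chol.T)


class TestPCA:
    def test_independent_columns_flat_spectrum(self):
        df = frame_from_matrix(np.random.default_rng(4).standard_normal((4000, 5)))
        lv = pca_first_component(df)
        assert np.all(np.abs(lv.eigenvalues - 1.0) < 0.2)
        assert lv.eigenvalues.sum() == pytest.approx(5.0, abs=1e-6)
        assert np.linalg.norm(lv.loadings) == pytest.approx(1.0, abs=1e-9)

    def test_equicorrelated_with_sign_pattern(self):
        """rho=0.4 equicorrelation (negative blocks for pd/wr/sa) has first
        eigenvalue 1 + 4*rho = 2.6 with equal-magnitude loadings."""
        signs = np.array([1, -1, -1, -1, 1.0])
        rho = 0.4 * np.outer(signs, signs)
        np.fill_diagonal(rho, 1.0)
        lv = pca_first_component(sample_correlated(rho, 20000, seed=5))
        assert lv.eigenvalues[0] == pytest.approx(2.6, abs=0.1)
        assert lv.loadings["fl"] > 0 and lv.loadings["ls"] > 0
        assert all(lv.loadings[s] < 0 for s in ("pd", "wr", "sa"))
        assert np.ptp(np.abs(lv.loadings)) < 0.06

    def test_second_eigenvalue_above_one_warns(self):
        # two separate tight blocks -> two eigenvalues above 1
        rho = np.eye(5)
        rho[0, 4] = rho[4, 0] = 0.9
        rho[1, 2] = rho[2, 1] = 0.9
        rho[1, 3] = rho[3, 1] = 0.9
        rho[2, 3] = rho[3, 2] = 0.9
        with pytest.warns(UserWarning, match="Kaiser"):
            pca_first_component(sample_correlated(rho, 3000, seed=6))

    def test_rank_deficiency_rejected(self):
        df = frame_from_matrix(np.random.default_rng(7).standard_normal((100, 5)))
        df["pd"] = df["fl"]
        with pytest.raises(DataError):
            pca_first_component(df)

    def test_needs_enough_rows(self):
        with pytest.raises(DataError):
            pca_first_component(frame_from_matrix(np.eye(5)[:4]))


class TestComputeWeights:
    def test_matches_bruteforce_double_loop(self):
        lv = reference_loadings()
        beta = reference_coefficients()
        got = compute_weights(lv, beta)
        raw = {}
        for comp in beta.columns:
            acc = 0.0
            for s in SCALES:
                acc += abs(lv.loadings[s] * beta.loc[s, comp])
            raw[comp] = acc / 5.0
        total = sum(raw.values())
        for comp in beta.columns:
            assert got.raw[comp] == pytest.approx(raw[comp], abs=1e-12)
            assert got.normalized[comp] == pytest.approx(raw[comp] / total, abs=1e-12)

    def test_reproduces_published_index_weights(self):
        got = compute_weights(reference_loadings(), reference_coefficients())
        for name, published in REFERENCE_WEIGHTS.items():
            assert got.normalized[name] == pytest.approx(published, abs=0.005)
        assert got.normalized.sum() == pytest.approx(1.0, abs=1e-9)
        assert got.normalized.nlargest(3).sum() == pytest.approx(REFERENCE_TOP3_SHARE, abs=0.01)

    def test_single_scale_term(self):
        lv = reference_loadings()
        beta = pd.DataFrame(0.0, index=list(SCALES), columns=["x"])
        lv.loadings["fl"] = 0.4
        beta.loc["fl", "x"] = 0.5
        got = compute_weights(lv, beta)
        assert got.raw["x"] == pytest.approx(abs(0.4 * 0.5) / 5)
        assert got.normalized["x"] == 1.0

    def test_scale_and_sign_invariance(self):
        lv = reference_loadings()
        beta = reference_coefficients()
        base = compute_weights(lv, beta).normalized
        flipped = LoadingVector(loadings=-lv.loadings, eigenvalues=lv.eigenvalues)
        pd.testing.assert_series_equal(compute_weights(flipped, beta).normalized, base)
        pd.testing.assert_series_equal(compute_weights(lv, beta * 7.5).normalized, base)

    def test_all_zero_coefficients_rejected(self):
        beta = pd.DataFrame(0.0, index=list(SCALES), columns=["a", "b"])
        with pytest.raises(DataError):
            compute_weights(reference_loadings(), beta)

    def test_single_benchmark_reduces_to_normalized_abs_beta(self):
        beta = pd.DataFrame([[0.4, -0.1, 0.2]], index=["peak_earnings"], columns=list("abc"))
        got = compute_weights(single_benchmark_loadings("peak_earnings"), beta)
        expect = np.abs(beta.iloc[0]) / np.abs(beta.iloc[0]).sum()
        np.testing.assert_allclose(got.normalized, expect, atol=1e-12)


class TestScoring:
    @pytest.fixture()
    def weights(self):
        return compute_weights(reference_loadings(), reference_coefficients(drop_all_zero=True))

    def test_bounds_and_linearity(self, weights):
        names = weights.names
        comp = pd.DataFrame(0.0, index=range(3), columns=names)
        comp.iloc[1] = 1.0
        comp.iloc[2, 0] = 1.0
        scores = score_index(comp, weights)
        assert scores.values.iloc[0] == 0.0
        assert scores.values.iloc[1] == pytest.approx(1.0)
        assert scores.values.iloc[2] == pytest.approx(weights.normalized.iloc[0])

    @given(arrays(np.int8, (8, 11), elements=st.integers(0, 1)))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_every_component(self, mat):
        weights = compute_weights(reference_loadings(), reference_coefficients(drop_all_zero=True))
        comp = pd.DataFrame(mat.astype(float), columns=weights.names)
        base = comp.to_numpy(float) @ weights.normalized.to_numpy()
        for j in range(comp.shape[1]):
            bumped = comp.copy()
            bumped.iloc[:, j] = 1.0
            new = bumped.to_numpy(float) @ weights.normalized.to_numpy()
            assert np.all(new >= base - 1e-15)

    def test_standardized_moments(self, weights):
        rng = np.random.default_rng(8)
        comp = pd.DataFrame(
            (rng.random((500, len(weights.names))) < 0.6).astype(float), columns=weights.names
        )
        scores = score_index(comp, weights)
        assert abs(scores.standardized.mean()) < 1e-9
        assert scores.standardized.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_unmatched_columns_reported(self, weights):
        comp = pd.DataFrame(0.0, index=range(4), columns=weights.names[:-2])
        with pytest.raises(DataError, match=weights.names[-1]):
            score_index(comp, weights)
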