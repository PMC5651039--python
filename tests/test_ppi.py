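"""Eigenvariates, PPI regressor construction, OLS GLM, edge matrices."""

import numpy as np
import pytest

from ppikit import (
    BoldSeries,
    HRFSpec,
    build_ppi_regressors,
    canonical_hrf,
    checkerboard_design,
    convolve_causal,
    edge_matrix,
    eigenvariate,
    fit_glm,
    sample_boxcar,
    symmetrize,
)


@pytest.fixture()
def slow_design():
    # 40 s-cycle block design on a 225-scan grid at TR 0.645 s
    return checkerboard_design(tr=0.645, n_scans=225, discard_leading=9.0)


class TestEigenvariate:
    def test_single_voxel_roi_reproduces_that_voxel(self, rng):
        voxel = rng.standard_normal(50)
        series = eigenvariate(voxel[:, None])
        r = np.corrcoef(series.values, voxel)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_block_recovers_shared_series(self, rng):
        u = rng.standard_normal(80)
        v = rng.uniform(0.5, 2.0, size=12)
        series = eigenvariate(np.outer(u, v))
        assert abs(np.corrcoef(series.values, u)[0, 1]) > 0.999

    def test_adjustment_removes_nuisance(self, rng):
        n = 100
        nuisance = rng.standard_normal(n)
        signal = rng.standard_normal(n)
        block = signal[:, None] + 0.8 * nuisance[:, None] + 0.05 * rng.standard_normal((n, 6))
        series = eigenvariate(block, adjust=nuisance[:, None])
        assert abs(np.corrcoef(series.values, nuisance)[0, 1]) < 0.01

    def test_sign_anchored_to_roi_mean(self, rng):
        block = np.abs(rng.standard_normal((60, 5))) + np.sin(np.arange(60))[:, None]
        series = eigenvariate(block)
        assert np.corrcoef(series.values, block.mean(axis=1))[0, 1] >= 0

    def test_zero_block_rejected(self):
        with pytest.raises(ValueError):
            eigenvariate(np.zeros((20, 3)))


class TestBuildPPIRegressors:
    @pytest.mark.parametrize("method", ["nondeconv", "deconv"])
    def test_zero_seed_gives_zero_ppi(self, slow_design, method):
        seed = BoldSeries(np.zeros(225), tr=0.645)
        design = build_ppi_regressors(seed, slow_design, method=method)
        assert np.allclose(design.ppi, 0)

    def test_psych_column_is_centered(self, slow_design, rng):
        seed = BoldSeries(rng.standard_normal(225), tr=0.645)
        design = build_ppi_regressors(seed, slow_design)
        assert abs(design.psych_conv.mean()) < 1e-12

    def test_nondeconv_term_is_exact_product(self, slow_design, rng):
        """The non-deconvolution term is bitwise the product of its factors."""
        seed = BoldSeries(rng.standard_normal(225), tr=0.645)
        design = build_ppi_regressors(seed, slow_design, method="nondeconv")
        spec = HRFSpec().at_dt(0.645)
        conv = convolve_causal(sample_boxcar(slow_design), canonical_hrf(spec), 0.645)
        expected = (conv - conv.mean()) * seed.values
        assert np.array_equal(design.ppi, expected)
        assert np.array_equal(design.physio, seed.values)

    def test_methods_agree_on_slow_block_design(self, slow_design, rng):
        """For a slow block design the two PPI terms are strongly correlated."""
        spec = HRFSpec()
        z = rng.standard_normal(225)
        seed = BoldSeries(
            convolve_causal(z, canonical_hrf(spec.at_dt(0.645)), 0.645), tr=0.645
        )
        d1 = build_ppi_regressors(seed, slow_design, spec, method="deconv")
        d2 = build_ppi_regressors(seed, slow_design, spec, method="nondeconv")
        assert np.corrcoef(d1.ppi, d2.ppi)[0, 1] > 0.8

    def test_grid_mismatch_rejected(self, slow_design):
        seed = BoldSeries(np.zeros(225), tr=1.4)
        with pytest.raises(ValueError):
            build_ppi_regressors(seed, slow_design)


class TestFitGLM:
    def test_perfect_fit_gives_unit_beta_and_sentinel_t(self, rng):
        x = np.column_stack([rng.standard_normal(30), np.ones(30)])
        y = x[:, 0].copy()
        with pytest.warns(UserWarning, match="perfect fit"):
            result = fit_glm(y, x, names=["slope", "constant"])
        assert result.betas[0] == pytest.approx(1.0)
        assert np.isinf(result.t[0])

    def test_betas_match_normal_equations_oracle(self, rng):
        x = np.column_stack([rng.standard_normal((20, 3)), np.ones(20)])
        y = rng.standard_normal(20)
        oracle = np.linalg.solve(x.T @ x, x.T @ y)
        result = fit_glm(y, x)
        assert np.allclose(result.betas, oracle, atol=1e-10)
        assert result.df == 20 - 4

    def test_duplicated_column_raises_naming_it(self, rng):
        base = rng.standard_normal((25, 2))
        x = np.column_stack([base, base[:, 0]])
        with pytest.raises(np.linalg.LinAlgError, match="x3"):
            fit_glm(rng.standard_normal(25), x)


class TestEdgeMatrix:
    def test_twenty_rois_give_190_unique_effects(self, slow_design, rng):
        series = [
            BoldSeries(rng.standard_normal(225), tr=0.645, label=f"roi{i}")
            for i in range(20)
        ]
        mat = edge_matrix(series, slow_design, method="nondeconv")
        assert mat.n_unique == 190
        assert mat.unique_effects().shape == (190,)
        assert np.all(np.isnan(np.diag(mat.values)))
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_symmetrize_of_symmetric_matrix_is_identity(self, rng):
        a = rng.standard_normal((5, 5))
        sym = (a + a.T) / 2
        out = symmetrize(sym.copy())
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(out[off], sym[off])

    def test_two_roi_value_is_mean_of_directed_betas(self, slow_design, rng):
        series = [
            BoldSeries(rng.standard_normal(225), tr=0.645, label=l) for l in "ab"
        ]
        mat = edge_matrix(series, slow_design, method="nondeconv")
        betas = []
        for i, j in ((0, 1), (1, 0)):
            design = build_ppi_regressors(series[i], slow_design, method="nondeconv")
            betas.append(fit_glm(series[j], design)["ppi"])
        assert mat.values[0, 1] == pytest.approx((betas[0] + betas[1]) / 2, rel=1e-10)

    def test_vectorized_path_matches_per_pair_fits(self, slow_design, rng):
        series = [
            BoldSeries(rng.standard_normal(225), tr=0.645, label=f"r{i}") for i in range(4)
        ]
        mat = edge_matrix(series, slow_design, method="nondeconv")
        for i in range(4):
            design = build_ppi_regressors(series[i], slow_design, method="nondeconv")
            for j in range(4):
                if i == j:
                    continue
                direct = fit_glm(series[j], design)["ppi"]
                back = fit_glm(
                    series[i],
                    build_ppi_regressors(series[j], slow_design, method="nondeconv"),
                )["ppi"]
                assert mat.values[i, j] == pytest.approx((direct + back) / 2, abs=1e-10)

    def test_relabelling_permutes_the_matrix(self, slow_design, rng):
        series = [
            BoldSeries(rng.standard_normal(225), tr=0.645, label=f"r{i}") for i in range(5)
        ]
        mat = edge_matrix(series, slow_design, method="nondeconv")
        perm = [3, 1, 4, 0, 2]
        mat_p = edge_matrix([series[k] for k in perm], slow_design, method="nondeconv")
        assert np.allclose(
            mat_p.values, mat.values[np.ix_(perm, perm)], equal_nan=True, atol=1e-12
        )
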