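"""Cohort-level EWAS: standardization, outlier fences, deconvolution,
surrogate variables and the per-CpG regression."""

import numpy as np
import pandas as pd
import pytest

import ewasmeta as em
from ewasmeta.errors import (DegenerateExposureError, InvalidConfigError,
                             StratumTooSmallError,
                             UnidentifiableReferenceError)
from ewasmeta.ewas import _ols_probe_block


class TestStandardizeBmi:
    def test_symmetric_triplet(self):
        assert np.allclose(em.standardize_bmi([20, 25, 30]), [-1, 0, 1])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateExposureError):
            em.standardize_bmi([22.6, 22.6])

    def test_matches_two_pass_oracle(self):
        x = np.array([26.6, 27.5, 28.0, 25.2])
        z = em.standardize_bmi(x)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert np.allclose(z, [(v - mean) / sd for v in x], atol=1e-12)
        assert abs(z.mean()) < 1e-12 and abs(z.std(ddof=1) - 1) < 1e-12

    def test_missing_propagates(self):
        z = em.standardize_bmi([20.0, np.nan, 30.0])
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2]]).all()


class TestTukeyOutliers:
    def test_constant_row_untouched(self):
        betas = pd.DataFrame([[0.5] * 10])
        cleaned, counts = em.remove_methylation_outliers(betas)
        assert counts.iloc[0] == 0
        assert (cleaned.to_numpy() == 0.5).all()

    def test_hand_oracle_bounds(self):
        # Q1=3, Q3=7 by linear interpolation, fences [-9, 19]: 1000 removed
        row = [1, 2, 3, 4, 5, 6, 7, 8, 1000]
        cleaned, counts = em.remove_methylation_outliers(pd.DataFrame([row]))
        assert counts.iloc[0] == 1
        assert np.isnan(cleaned.iloc[0, 8])
        assert np.isfinite(cleaned.iloc[0, :8]).all()

    def test_single_far_outlier_in_tight_distribution(self):
        rng = np.random.default_rng(0)
        row = rng.beta(50, 50, 1000) * 0.1 + 0.2  # tight around 0.25
        row[123] = 0.99
        cleaned, counts = em.remove_methylation_outliers(pd.DataFrame([row]))
        assert counts.iloc[0] == 1
        assert np.isnan(cleaned.iloc[0, 123])

    def test_short_rows_skipped(self):
        betas = pd.DataFrame([[0.1, 0.2, np.nan, np.nan, np.nan]])
        cleaned, counts = em.remove_methylation_outliers(betas)
        assert counts.iloc[0] == 0


class TestCellDeconvolution:
    def _ref(self, n_probes=50, k=3, seed=0):
        return em.generate_cell_reference(n_probes, k, seed=seed,
                                          discriminating_fraction=1.0)

    def test_vertex_sample_recovered(self):
        ref = self._ref()
        betas = ref.profiles.iloc[:, [0]].copy()
        betas.columns = ["s1"]
        est = em.estimate_cell_proportions(betas, ref)
        assert np.allclose(est.to_numpy(), [[1, 0, 0]], atol=1e-8)

    def test_exact_two_component_mixture(self):
        ref = self._ref()
        mix = 0.6 * ref.profiles.iloc[:, 0] + 0.4 * ref.profiles.iloc[:, 1]
        est = em.estimate_cell_proportions(mix.to_frame("s1"), ref)
        assert np.allclose(est.to_numpy(), [[0.6, 0.4, 0.0]], atol=1e-8)

    def test_noisy_mixtures_mae_below_003(self):
        ref = em.generate_cell_reference(200, 7, seed=2,
                                         discriminating_fraction=1.0)
        rng = np.random.default_rng(3)
        truth = rng.dirichlet(np.ones(7) * 5, size=50)
        y = ref.profiles.to_numpy() @ truth.T + rng.normal(0, 0.01, (200, 50))
        betas = pd.DataFrame(np.clip(y, 0, 1), index=ref.probe_ids)
        est = em.estimate_cell_proportions(betas, ref)
        assert np.abs(est.to_numpy() - truth).mean() < 0.03

    def test_rank_deficient_reference_rejected(self):
        profiles = pd.DataFrame(
            np.tile(np.linspace(0.1, 0.9, 20)[:, None], (1, 3)),
            index=[f"cg{i:08d}" for i in range(20)],
            columns=["a", "b", "c"])
        ref = em.CellReference(profiles)
        betas = pd.DataFrame(np.full((20, 4), 0.5), index=profiles.index)
        with pytest.raises(UnidentifiableReferenceError):
            em.estimate_cell_proportions(betas, ref)


class TestSurrogateVariables:
    def test_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        betas = pd.DataFrame(rng.normal(0.5, 0.05, (300, 80)))
        design = np.column_stack([np.ones(80), rng.normal(size=(80, 3))])
        svs = em.estimate_surrogate_variables(betas, design, 4)
        assert np.abs(svs.T @ design).max() < 1e-8

    def test_planted_batch_factor_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        factor = rng.normal(size=n)
        affected = rng.random(1000) < 0.3
        load = np.where(affected, rng.normal(0, 0.05, 1000), 0.0)
        y = 0.5 + load[:, None] * factor[None, :] + \
            rng.normal(0, 0.02, (1000, n))
        svs = em.estimate_surrogate_variables(
            pd.DataFrame(y), np.ones((n, 1)), 1)
        assert abs(np.corrcoef(svs[:, 0], factor)[0, 1]) > 0.9

    def test_pure_noise_svs_match_permutation_oracle(self):
        """With no latent structure, top-k SVs capture no more residual
        variance than the same SVD applied to row-permuted residuals."""
        rng = np.random.default_rng(4)
        n, p, k = 100, 500, 2
        design = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = design @ rng.normal(size=(3, p)) * 0.1 + \
            rng.normal(0, 1.0, (n, p))
        betas = pd.DataFrame(y.T)
        resid = betas.to_numpy() - (design @ np.linalg.lstsq(
            design, betas.to_numpy().T, rcond=None)[0]).T
        svs = em.estimate_surrogate_variables(betas, design, k)
        captured = ((resid @ svs) ** 2).sum()
        perm = resid.copy()
        for row in perm:
            rng.shuffle(row)
        perm_svs = em.estimate_surrogate_variables(
            pd.DataFrame(perm), design, k)
        perm_captured = ((perm @ perm_svs) ** 2).sum()
        assert captured < perm_captured * 1.1

    def test_k_too_large_rejected(self):
        betas = pd.DataFrame(np.random.default_rng(0).random((50, 10)))
        with pytest.raises(InvalidConfigError):
            em.estimate_surrogate_variables(betas, np.ones((10, 1)), 9)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(5)
        betas = pd.DataFrame(rng.normal(0.5, 0.05, (200, 40)))
        a = em.estimate_surrogate_variables(betas, np.ones((40, 1)), 3)
        b = em.estimate_surrogate_variables(betas, np.ones((40, 1)), 3)
        assert np.array_equal(a, b)
        for j in range(3):
            nz = np.nonzero(np.abs(a[:, j]) > 1e-12)[0]
            assert a[nz[0], j] > 0


class TestOlsCore:
    def test_three_point_hand_oracle(self):
        # y = [1,2,2]/100 on x = [0,1,2]: slope 0.005, known closed form
        x = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        y = np.array([[0.01, 0.02, 0.02]])
        b, se, p, df = _ols_probe_block(x, y, 1)
        assert np.isclose(b[0], 0.005)
        # hand SE: residuals (±1/600), sigma2 = sum r^2 / 1, Sxx = 2
        resid = y[0] - x @ np.linalg.lstsq(x, y[0], rcond=None)[0]
        sigma2 = (resid ** 2).sum() / 1
        assert np.isclose(se[0], np.sqrt(sigma2 / 2.0), rtol=1e-12)
        assert df == 1


class TestRunEwas:
    def test_injected_effect_recovered(self, reference_2000):
        probe = em.select_effect_probes(reference_2000, 1, seed=1)[0]
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(1000,), n_probes=2000, seed=21,
            effect_specs=(em.EffectSpec(probe, "paternal", 0.5),))
        ds, _ = em.generate_consortium(cfg, reference=reference_2000)
        res = em.run_ewas(ds[0], em.EwasModelSpec(), reference_2000)
        row = res.table.loc[probe]
        assert abs(row["beta"] - 0.5) < 3 * row["se"]
        assert row["n"] == 1000

    def test_null_p_values_uniform(self, small_null_consortium,
                                   reference_2000):
        _, datasets = small_null_consortium
        res = em.run_ewas(datasets[0], em.EwasModelSpec(), reference_2000)
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_small_sex_stratum_rejected(self, reference_2000):
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(60,), n_probes=2000, seed=13)
        ds, _ = em.generate_consortium(cfg, reference=reference_2000)
        model = em.EwasModelSpec(sex_stratum="female",
                                 n_surrogate_variables=0)
        with pytest.raises(StratumTooSmallError):
            em.run_ewas(ds[0], model, reference_2000, min_stratum_size=50)

    def test_mutual_adjustment_noop_when_exposures_orthogonal(
            self, reference_2000):
        """With the other parent's BMI constructed orthogonal (in-sample)
        to every unadjusted design column, the mutually adjusted and
        unadjusted exposure estimates coincide exactly."""
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(200,), n_probes=2000, seed=31)
        ds, _ = em.generate_consortium(cfg, reference=reference_2000)
        model_u = em.EwasModelSpec(n_surrogate_variables=0)
        res_u = em.run_ewas(ds[0], model_u, reference_2000,
                            remove_outliers=False)
        # rebuild the unadjusted design and orthogonalize maternal BMI to it
        pheno = ds[0].phenotypes
        z = em.standardize_bmi(pheno["paternal_bmi"])
        cells = em.estimate_cell_proportions(ds[0].betas, reference_2000)
        x = np.column_stack(
            [np.ones(200), z,
             pheno[list(em.ewas.COVARIATES)].to_numpy(dtype=float),
             cells.to_numpy()[:, :-1]])
        raw = np.random.default_rng(1).normal(size=200)
        resid = raw - x @ np.linalg.lstsq(x, raw, rcond=None)[0]
        pheno2 = pheno.copy()
        pheno2["maternal_bmi"] = 24.0 + resid
        ds2 = em.CohortDataset(ds[0].cohort_id, ds[0].betas, pheno2,
                               ds[0].true_cell_proportions)
        model_a = em.EwasModelSpec(mutual_adjustment=True,
                                   n_surrogate_variables=0)
        res_a = em.run_ewas(ds2, model_a, reference_2000,
                            remove_outliers=False)
        assert np.allclose(res_u.table["beta"], res_a.table["beta"],
                           atol=1e-10)

    def test_per_probe_n_counts_complete_cases(self, reference_2000):
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(150,), n_probes=2000, seed=17,
            missing_rate=0.02)
        ds, _ = em.generate_consortium(cfg, reference=reference_2000)
        res = em.run_ewas(ds[0], em.EwasModelSpec(n_surrogate_variables=5),
                          reference_2000, remove_outliers=False)
        nonmiss = ds[0].betas.notna().sum(axis=1)
        common = res.table.index
        assert (res.table.loc[common, "n"] <= nonmiss.loc[common]).all()
        assert (res.table["n"] <= 150).all()


class TestCellRegression:
    def test_noise_free_line_recovered_exactly(self, reference_2000):
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(100,), n_probes=2000, seed=23)
        ds, _ = em.generate_consortium(cfg, reference=reference_2000)
        z = em.standardize_bmi(ds[0].phenotypes["paternal_bmi"])
        est = pd.DataFrame({"cellA": 0.2 + 0.001 * z},
                           index=ds[0].betas.columns)
        out = em.regress_cell_on_bmi(ds[0], est)
        assert np.isclose(out.loc["cellA", "estimate"], 0.001, atol=1e-12)

    def test_type_one_error_calibrated(self, reference_2000):
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(500,), n_probes=2000, seed=29)
        ds, _ = em.generate_consortium(cfg, reference=reference_2000)
        rng = np.random.default_rng(0)
        # 500 independent null "cell types" = 500 replicate regressions
        est = pd.DataFrame(rng.normal(0.2, 0.02, (500, 500)),
                           index=ds[0].betas.columns,
                           columns=[f"c{i}" for i in range(500)])
        out = em.regress_cell_on_bmi(ds[0], est)
        frac = (out["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestParentalCorrelation:
    def test_monotone_pairs(self):
        pheno = pd.DataFrame({
            "paternal_bmi": [20, 22, 25, 28, 30.0],
            "maternal_bmi": [19, 21, 23, 27, 29.0],
        }, index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"))
        for col in ("paternal_age", "maternal_age", "maternal_smoking",
                    "paternal_smoking", "parity", "paternal_sep"):
            pheno[col] = 0.0
        pheno["child_sex"] = "female"
        betas = pd.DataFrame(np.full((3, 5), 0.5), columns=pheno.index)
        ds = em.CohortDataset("toy", betas, pheno)
        rho, _ = em.parental_bmi_correlation(ds)
        assert rho == pytest.approx(1.0)
        pheno2 = pheno.copy()
        pheno2["maternal_bmi"] = pheno["maternal_bmi"].to_numpy()[::-1]
        rho2, _ = em.parental_bmi_correlation(
            em.CohortDataset("toy", betas, pheno2))
        assert rho2 == pytest.approx(-1.0)

    def test_configured_correlation_recovered_at_largest_cohort_size(self):
        cfg = em.SimulationConfig(
            n_cohorts=1, cohort_sizes=(982,), n_probes=20,
            parent_bmi_correlation=0.2, seed=37)
        ds, _ = em.generate_consortium(cfg)
        rho, p = em.parental_bmi_correlation(ds[0])
        assert abs(rho - 0.2) < 0.08
        assert p < 0.05
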