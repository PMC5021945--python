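"""Tests of the synthetic-cohort generator against its ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ffpesig import (SimulationConfig, compute_qc, km_estimate, make_signature,
                     render_array_platform, render_count_platform, screen_genes,
                     simulate_cohort, simulate_latent_expression, simulate_survival)
from ffpesig.core import ConfigurationError

from conftest import clinical_frame


class TestConfig:
    @pytest.mark.parametrize("field, value", [
        ("n_samples", 0), ("n_genes", -1), ("n_prognostic", -2),
        ("log_hr_magnitude", 0.0), ("baseline_hazard", -0.1),
        ("censor_rate", 1.5), ("frac_low_quality", -0.1),
        ("count_dispersion", 0.0), ("n_probes_per_gene", 0),
        ("batch_shift_sd", -1.0), ("module_corr", 0.0),
    ])
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**{field: value})

    def test_prognostic_cannot_exceed_genes(self):
        with pytest.raises(ConfigurationError, match="n_prognostic"):
            SimulationConfig(n_genes=10, n_prognostic=11)


class TestLatent:
    def test_zero_noise_columns_all_equal_gene_means(self):
        cfg = SimulationConfig(n_samples=8, n_genes=12, n_prognostic=0,
                               batch_shift_sd=0.0, noise_sd=0.0, seed=5)
        latent, _ = simulate_latent_expression(cfg)
        np.testing.assert_array_equal(latent.to_numpy(),
                                      np.tile(latent.iloc[:, [0]], (1, 8)))

    def test_bit_identical_given_seed(self):
        cfg = SimulationConfig(n_samples=10, n_genes=15, n_prognostic=3, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.latent, b.latent)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert a.truth.true_log_hr == b.truth.true_log_hr

    def test_batch_column_means_match_drawn_offsets(self):
        cfg = SimulationConfig(n_samples=400, n_genes=50, n_prognostic=0,
                               n_batches=2, batch_shift_sd=2.0, noise_sd=1.0, seed=3)
        latent, truth = simulate_latent_expression(cfg)
        labels = pd.Series(truth.batch_assignments)
        b1 = latent.loc[:, labels[labels == "B1"].index].mean(axis=1)
        b2 = latent.loc[:, labels[labels == "B2"].index].mean(axis=1)
        observed = (b1 - b2).to_numpy()
        expected = (truth.batch_offsets["B1"] - truth.batch_offsets["B2"]).to_numpy()
        se = cfg.noise_sd * np.sqrt(1 / (labels == "B1").sum() + 1 / (labels == "B2").sum())
        assert np.all(np.abs(observed - expected) < 3.3 * se)

    def test_direction_consistent_with_sign(self):
        _, truth = simulate_latent_expression(SimulationConfig(seed=2))
        for g in truth.prognostic_gene_ids:
            assert truth.true_direction[g] == ("up" if truth.true_log_hr[g] > 0 else "down")


class TestSurvival:
    def test_null_cohort_km_matches_exponential(self):
        cfg = SimulationConfig(n_samples=2000, n_genes=5, n_prognostic=0,
                               censor_rate=0.0, baseline_hazard=0.02, seed=4)
        latent, truth = simulate_latent_expression(cfg)
        table = simulate_survival(latent, truth, cfg)
        curve = km_estimate(table["os_time_months"], table["os_event"])
        theoretical = np.exp(-cfg.baseline_hazard * curve.times)
        assert np.max(np.abs(curve.survival - theoretical)) < 0.05

    def test_zero_effect_equals_null_distribution(self):
        # log_hr_magnitude -> 0 limit: linear predictor identically zero
        cfg = SimulationConfig(n_samples=50, n_genes=10, n_prognostic=5,
                               log_hr_magnitude=1e-300, seed=6)
        _, truth = simulate_latent_expression(cfg)
        assert np.allclose(truth.linear_predictor, 0.0, atol=1e-290)

    def test_full_censoring_means_no_events(self):
        cfg = SimulationConfig(n_samples=40, n_genes=5, n_prognostic=0,
                               censor_rate=1.0, seed=8)
        latent, truth = simulate_latent_expression(cfg)
        table = simulate_survival(latent, truth, cfg)
        assert table["os_event"].sum() == 0 and table["dfs_event"].sum() == 0
        assert (table[["os_time_months", "dfs_time_months"]] > 0).all().all()

    def test_target_censoring_fraction_roughly_met(self):
        cfg = SimulationConfig(n_samples=3000, n_genes=5, n_prognostic=0,
                               censor_rate=0.4, seed=9)
        latent, truth = simulate_latent_expression(cfg)
        table = simulate_survival(latent, truth, cfg)
        assert abs((1 - table["os_event"]).mean() - 0.4) < 0.05


class TestCountPlatform:
    def test_counts_are_nonnegative_integers(self, small_cohort):
        vals = small_cohort.counts.to_numpy()
        assert np.all(vals >= 0)
        assert np.issubdtype(small_cohort.counts.dtypes.iloc[0], np.integer)

    def test_good_samples_all_pass_qc(self):
        cfg = SimulationConfig(n_samples=20, n_genes=50, n_prognostic=0,
                               frac_low_quality=0.0, seed=10)
        latent, _ = simulate_latent_expression(cfg)
        counts, controls = render_count_platform(latent, cfg)
        report = compute_qc(counts, controls)
        assert report.summary["pass"].all()

    def test_poisson_limit_variance_over_mean_near_one(self):
        # negative controls have constant mean across samples; at tiny
        # dispersion the draw is effectively Poisson
        cfg = SimulationConfig(n_samples=1000, n_genes=5, n_prognostic=0,
                               count_dispersion=1e-6, frac_low_quality=0.0,
                               neg_control_mean=50.0, seed=11)
        latent, _ = simulate_latent_expression(cfg)
        counts, controls = render_count_platform(latent, cfg)
        neg = counts.loc[sorted(controls.negative)].to_numpy()
        ratio = neg.var(axis=1, ddof=1) / neg.mean(axis=1)
        assert np.all((ratio > 0.8) & (ratio < 1.2))

    def test_zero_background_counts_only_zeros_as_missing(self):
        cfg = SimulationConfig(n_samples=12, n_genes=30, n_prognostic=0,
                               neg_control_mean=0.0, frac_low_quality=0.0, seed=12)
        latent, _ = simulate_latent_expression(cfg)
        counts, controls = render_count_platform(latent, cfg)
        report = compute_qc(counts, controls)
        endo = counts.drop(index=sorted(controls.all))
        np.testing.assert_allclose(report.summary["missing_rate"],
                                   (endo == 0).mean(axis=0))


class TestArrayPlatform:
    def test_single_noiseless_probe_is_identity(self):
        cfg = SimulationConfig(n_samples=10, n_genes=20, n_prognostic=0,
                               n_probes_per_gene=1, array_noise_sd=0.0,
                               probe_affinity_sd=0.0, n_multigene_probes=0, seed=13)
        latent, _ = simulate_latent_expression(cfg)
        probes, probe_map = render_array_platform(latent, cfg)
        np.testing.assert_allclose(probes.to_numpy(), latent.to_numpy())
        assert all(len(v) == 1 for v in probe_map.values())

    def test_multigene_probe_count(self):
        cfg = SimulationConfig(n_samples=8, n_genes=15, n_prognostic=0,
                               n_multigene_probes=4, seed=14)
        latent, _ = simulate_latent_expression(cfg)
        probes, probe_map = render_array_platform(latent, cfg)
        multi = [p for p, gs in probe_map.items() if len(set(gs)) > 1]
        assert len(multi) == 4
        assert probes.shape[0] == 15 * cfg.n_probes_per_gene + 4


class TestMakeSignature:
    def test_pure_true_signature_copies_directions(self, small_cohort):
        sig = make_signature(small_cohort.truth, n_true=5, n_noise=0, seed=3)
        assert set(sig.genes) <= small_cohort.truth.prognostic_gene_ids
        for g in sig.genes:
            assert sig.direction[g] == small_cohort.truth.true_direction[g]

    def test_deterministic_given_seed(self, small_cohort):
        a = make_signature(small_cohort.truth, 3, 4, seed=9)
        b = make_signature(small_cohort.truth, 3, 4, seed=9)
        assert a.genes == b.genes and a.direction == b.direction

    def test_too_many_true_genes_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError, match="n_true"):
            make_signature(small_cohort.truth, n_true=99, n_noise=0, seed=0)


class TestMarginalRecovery:
    def test_fitted_sign_matches_truth_for_most_prognostic_genes(self):
        # moderate cohort: at least 90% of prognostic genes should get a
        # fitted marginal log HR with the true sign
        cfg = SimulationConfig(n_samples=400, n_genes=100, n_prognostic=20,
                               noise_sd=0.5, log_hr_magnitude=1.0,
                               batch_shift_sd=0.0, seed=15)
        latent, truth = simulate_latent_expression(cfg)
        table = simulate_survival(latent, truth, cfg)
        res = screen_genes(latent, table, "OS")
        prog = sorted(truth.prognostic_gene_ids)
        fitted = np.sign(res.loc[prog, "log_hr"].to_numpy())
        wanted = np.sign([truth.true_log_hr[g] for g in prog])
        assert (fitted == wanted).mean() >= 0.9
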