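"""Limited-sampling-strategy evaluation: metrics and pipeline properties."""

import numpy as np
import pytest

import drvoss as d


class TestComputeMetrics:
    def test_hand_computed_example(self):
        m = d.compute_metrics([100, 100, 100, 100], [90, 110, 80, 120])
        assert m.mpe_pct == pytest.approx(0.0)
        assert m.rmspe_pct == pytest.approx(
            100 * np.sqrt((0.1**2 + 0.1**2 + 0.2**2 + 0.2**2) / 4)
        )  # 15.81%
        assert m.frac_within_15 == pytest.approx(0.5)

    def test_identity_predictions(self):
        ref = np.array([60.0, 80.0, 100.0, 55.0])
        m = d.compute_metrics(ref, ref)
        assert (m.rho, m.mpe_pct, m.rmspe_pct, m.frac_within_15) == (1.0, 0.0, 0.0, 1.0)

    def test_rank_invariance_under_monotone_scaling(self):
        ref = np.array([60.0, 80.0, 100.0, 55.0])
        m = d.compute_metrics(ref, 2 * ref)
        assert m.rho == pytest.approx(1.0)
        assert m.rmspe_pct == pytest.approx(100.0)
        assert m.frac_within_15 == 0.0

    def test_jensen_inequality_on_random_vectors(self, rng):
        for _ in range(20):
            ref = rng.uniform(40, 150, 50)
            oss = ref * rng.lognormal(0, 0.3, 50)
            m = d.compute_metrics(ref, oss)
            assert m.rmspe_pct**2 >= m.mpe_pct**2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            d.compute_metrics([1.0], [1.0])
        with pytest.raises(ValueError):
            d.compute_metrics([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            d.compute_metrics([-1, 2], [1, 2])


class TestSamplingStrategy:
    def test_validation(self):
        s = d.SamplingStrategy.from_times([19, 1, 4])
        assert s.times == (1.0, 4.0, 19.0)
        assert s.name == "C1-C4-C19"
        with pytest.raises(ValueError):
            d.SamplingStrategy("x", (1, 1))
        with pytest.raises(ValueError):
            d.SamplingStrategy("x", (0, 1, 2, 3, 4))
        with pytest.raises(ValueError):
            d.SamplingStrategy("x", (25.0,))


class TestEvaluateStrategy:
    def test_noise_free_identifiability_rich_design(self, pop):
        """With vanishing residual error the rich design recovers every AUC."""
        sharp = pop.replace(sigma_exp=1e-5, sigma_add=1e-5)
        subjects = d.sample_covariates(10, rng_seed=4)
        strat = d.SamplingStrategy.from_times([0, 0.5, 1, 2, 3, 4, 5, 6][:4])
        ev = d.evaluate_strategy(sharp, subjects, strat, n_rep=5, rng_seed=6)
        assert ev.metrics.frac_within_15 == 1.0
        assert ev.metrics.rmspe_pct < 1.0

    def test_residual_noise_alone_gives_centred_pe(self, pop):
        """Profiles simulated without IIV but fitted with the full prior:
        prediction errors come from residual noise only and are centred."""
        from drvoss.mapfit import fit_many
        import numpy as np

        pop0 = pop.replace(omega_cl=0, omega_v=0, omega_ka=0)
        subjects = [(c, r) for c, r in d.sample_covariates(100, rng_seed=4)]
        sim = d.simulate_profiles(pop0, subjects, 5, [1.0, 4.0, 19.0], rng_seed=6)
        wide = sim.pivot_table(index=["ID", "REP"], columns="TAD", values="DV")
        meta = sim.drop_duplicates(["ID", "REP"]).set_index(["ID", "REP"]).loc[wide.index]
        eta, _, _ = fit_many(
            pop, np.array([1.0, 4.0, 19.0]), wide.to_numpy(),
            meta["CL"].to_numpy(), meta["V"].to_numpy(), meta["KA"].to_numpy(),
            meta["AMT"].to_numpy(), meta["II"].to_numpy(),
        )
        auc_oss = meta["AMT"].to_numpy() * 24 / meta["II"].to_numpy() / (
            meta["CL"].to_numpy() * np.exp(eta[:, 0])
        )
        m = d.compute_metrics(meta["AUC24"].to_numpy(), auc_oss)
        assert abs(m.mpe_pct) < 5.0
        assert m.rmspe_pct > 0.5

    def test_zero_iiv_identified_exactly(self, pop):
        """With no IIV the prior pins every estimate at the typical value,
        which is also the truth: all prediction errors vanish."""
        pop0 = pop.replace(omega_cl=0, omega_v=0, omega_ka=0)
        subjects = d.sample_covariates(30, rng_seed=4)
        strat = d.SamplingStrategy.from_times([1, 4, 19])
        ev = d.evaluate_strategy(pop0, subjects, strat, n_rep=2, rng_seed=6,
                                 residual_error=True)
        assert ev.metrics.rmspe_pct == 0.0 and ev.metrics.mpe_pct == 0.0

    def test_more_sampling_information_helps(self, pop):
        """RMSPE({0,1,4}) <= RMSPE({0,1}) <= RMSPE({0}) (1-point slack)."""
        subjects = d.sample_covariates(40, rng_seed=9)
        rms = []
        for times in ([0.0], [0.0, 1.0], [0.0, 1.0, 4.0]):
            ev = d.evaluate_strategy(
                pop, subjects, d.SamplingStrategy.from_times(times), n_rep=250, rng_seed=10
            )
            rms.append(ev.metrics.rmspe_pct)
        assert rms[2] <= rms[1] + 1.0
        assert rms[1] <= rms[0] + 1.0

    def test_metrics_invariant_under_common_unit_scaling(self, pop):
        """Rescaling doses and concentrations (and the additive error with
        them) leaves every metric unchanged."""
        subjects = [(c, d.Regimen(r.dose, r.tau)) for c, r in d.sample_covariates(15, rng_seed=2)]
        strat = d.SamplingStrategy.from_times([1, 4, 19])
        ev1 = d.evaluate_strategy(pop, subjects, strat, 4, rng_seed=3)
        k = 10.0
        pop_scaled = pop.replace(sigma_add=pop.sigma_add * k)
        scaled = [(c, d.Regimen(r.dose * k, r.tau)) for c, r in subjects]
        ev2 = d.evaluate_strategy(pop_scaled, scaled, strat, 4, rng_seed=3)
        assert ev1.metrics.rho == pytest.approx(ev2.metrics.rho, abs=1e-9)
        assert ev1.metrics.rmspe_pct == pytest.approx(ev2.metrics.rmspe_pct, abs=1e-6)

    def test_jensen_on_pipeline_output(self, pop):
        subjects = d.sample_covariates(20, rng_seed=5)
        ev = d.evaluate_strategy(pop, subjects, d.SamplingStrategy.from_times([0]), 10, 1)
        assert ev.metrics.rmspe_pct**2 >= ev.metrics.mpe_pct**2


class TestCompareStrategies:
    def test_single_strategy_matches_evaluate(self, pop):
        subjects = d.sample_covariates(12, rng_seed=3)
        strat = d.SamplingStrategy.from_times([0, 4])
        report, evs = d.compare_strategies(pop, subjects, [strat], 5, rng_seed=4)
        direct = d.evaluate_strategy(pop, subjects, strat, 5, rng_seed=4)
        assert len(report) == 1
        assert report.loc[0, "rho"] == pytest.approx(direct.metrics.rho)
        assert report.loc[0, "RMSPE"] == pytest.approx(direct.metrics.rmspe_pct)

    def test_duplicate_names_rejected(self, pop):
        subjects = d.sample_covariates(5, rng_seed=3)
        s = d.SamplingStrategy.from_times([1])
        with pytest.raises(ValueError, match="duplicate"):
            d.compare_strategies(pop, subjects, [s, s], 2, 1)

    def test_same_master_seed_reproducible(self, pop):
        subjects = d.sample_covariates(8, rng_seed=3)
        strats = [d.SamplingStrategy.from_times(t) for t in ([0], [1, 4])]
        r1, _ = d.compare_strategies(pop, subjects, strats, 3, rng_seed=11)
        r2, _ = d.compare_strategies(pop, subjects, strats, 3, rng_seed=11)
        assert r1.equals(r2)

    def test_bland_altman_coordinates_exported(self, pop):
        subjects = d.sample_covariates(6, rng_seed=3)
        _, evs = d.compare_strategies(
            pop, subjects, [d.SamplingStrategy.from_times([0, 4])], 3, 1
        )
        t = next(iter(evs.values())).table
        assert {"ba_mean", "ba_diff"} <= set(t.columns)
        assert np.allclose(t.ba_mean, (t.AUC_ref + t.AUC_OSS) / 2)
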