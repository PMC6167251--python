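"""Tests for MCMC sampling, model fitting and discrimination."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from egfrptp.compartment_kinetics import (
    DOSE_SERIES_NG_ML,
    BindingModel,
    bound_fraction_depletion,
    ng_ml_to_molar,
)
from egfrptp.inference import (
    MCMCConfig,
    adaptive_mh_sample,
    aic,
    fit_binding_kd,
    fit_dose_response_model,
    fit_recycling,
    fit_specific_activity,
    remove_outliers_mad,
    select_model,
)
from egfrptp.reaction_models import ReactionParams, pegfr_dose_response
from egfrptp.synthetic_data import (
    DEFAULT_KD_MOLAR,
    CohortConfig,
    synth_dose_response_cells,
    synth_recycling_traces,
)


class TestAdaptiveMH:
    def test_standard_normal_moments(self):
        cfg = MCMCConfig(n_steps=50_000, initial=[0.0],
                         bounds=[(-10.0, 10.0)], burn_in=5000, seed=0,
                         proposal_scale=1.0)
        chain, stats = adaptive_mh_sample(lambda x: -0.5 * x[0] ** 2, cfg)
        assert abs(chain.mean()) < 0.05
        assert chain.var() == pytest.approx(1.0, rel=0.10)
        assert 0.1 < stats["acceptance_rate"] < 0.8

    def test_correlated_normal_recovers_correlation(self):
        rho = 0.8
        prec = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))

        def logp(x):
            return -0.5 * x @ prec @ x

        cfg = MCMCConfig(n_steps=60_000, initial=[0.0, 0.0],
                         bounds=[(-10, 10), (-10, 10)], burn_in=10_000,
                         seed=1, proposal_scale=0.5)
        chain, _ = adaptive_mh_sample(logp, cfg)
        got = np.corrcoef(chain.T)[0, 1]
        assert got == pytest.approx(rho, abs=0.05)

    def test_same_seed_reproduces_chain(self):
        cfg = MCMCConfig(n_steps=3000, initial=[0.5],
                         bounds=[(-5.0, 5.0)], seed=7)
        c1, _ = adaptive_mh_sample(lambda x: -0.5 * x[0] ** 2, cfg)
        c2, _ = adaptive_mh_sample(lambda x: -0.5 * x[0] ** 2, cfg)
        assert np.array_equal(c1, c2)

    def test_chain_moments_stable_across_seed_sets(self):
        def run(seed):
            cfg = MCMCConfig(n_steps=30_000, initial=[0.0],
                             bounds=[(-10, 10)], burn_in=5000, seed=seed,
                             proposal_scale=1.0)
            chain, _ = adaptive_mh_sample(lambda x: -0.5 * x[0] ** 2, cfg)
            return chain.mean(), chain.std()

        m1, s1 = run(11)
        m2, s2 = run(12)
        mc_se = 1.0 / np.sqrt(25_000 / 10)   # rough effective-sample SE
        assert abs(m1 - m2) < 2 * 2 * mc_se
        assert abs(s1 - s2) < 0.1

    def test_infinite_initial_rejected(self):
        cfg = MCMCConfig(n_steps=100, initial=[0.0], bounds=[(-1, 1)])
        with pytest.raises(ValueError):
            adaptive_mh_sample(lambda x: -np.inf, cfg)

    def test_all_rejected_warmup_raises(self):
        cfg = MCMCConfig(n_steps=2000, initial=[0.0], bounds=[(-1, 1)],
                         adapt_start=200, proposal_scale=0.5, seed=3)

        def spike(x):
            # finite only within a region far narrower than the proposal
            return 0.0 if abs(x[0]) < 1e-12 else -np.inf

        with pytest.raises(RuntimeError, match="warm-up"):
            adaptive_mh_sample(spike, cfg)


class TestAic:
    def test_recomputation_matches(self):
        got = aic(rss=0.5, n_obs=40, n_params=3)
        assert got == pytest.approx(40 * np.log(0.5 / 40) + 6)

    def test_small_sample_correction_larger(self):
        assert aic(0.5, 12, 4, corrected=True) > aic(0.5, 12, 4)


class TestDoseResponseFit:
    def test_noiseless_self_fit_recovers_curve_and_params(self):
        # generate in the fitter's own parameter space
        gen = ReactionParams(alpha1=0.01, alpha2=0.8, alpha3=0.9, gamma=1.0,
                             k1=1.0, k2=0.5, k3=0.0, k4=0.0, k5=2.0,
                             ptp_total=1.0,
                             topology="negative_regulation")
        lf = np.linspace(0.0, 0.9, 10)
        curve = pegfr_dose_response(gen, lf)
        fit = fit_dose_response_model([(lf, curve)], "negative_regulation",
                                      seed=0, mcmc_steps=3000)
        assert fit.rss < 1e-8
        # individual rates sit on a time-scale ridge; the autocatalysis
        # ratio alpha2/alpha3 is identifiable and must be covered
        names = ["alpha1", "alpha2", "alpha3", "k2", "k5"]
        i2, i3 = names.index("alpha2"), names.index("alpha3")
        ratio = 10.0 ** (fit.chain[:, i2] - fit.chain[:, i3])
        lo, hi = np.quantile(ratio, [0.025, 0.975])
        assert lo - 1e-6 <= 0.8 / 0.9 <= hi + 1e-6
        # and the fitted curve reproduces the generating curve
        p_hat = ReactionParams(
            **{k: fit.params[k] for k in names}, gamma=1.0, k1=1.0,
            ptp_total=1.0, k3=0.0, k4=0.0, topology="negative_regulation")
        assert np.allclose(pegfr_dose_response(p_hat, lf), curve, atol=1e-4)

    def test_switch_location_recovered_within_grid_step(self):
        gen = ReactionParams(alpha3=0.1, ptp_total=2.3, k3=8.0)
        cfg = CohortConfig(n_cells=10, params=gen, noise_sd=0.02,
                           param_cv=0.0, depletion_molar=2e-9, seed=4)
        cells, truth = synth_dose_response_cells(cfg)
        fit = fit_dose_response_model(cells, "double_negative", seed=0,
                                      n_starts=3)
        lf = truth["liganded_fractions"]
        p_hat = ReactionParams(
            **{k: fit.params.get(k, 0.0)
               for k in ("alpha1", "alpha2", "alpha3", "k2", "k3", "k5")},
            gamma=1.0, k1=1.0, ptp_total=1.0, topology="double_negative")
        pred = pegfr_dose_response(p_hat, lf)
        true_curve = pegfr_dose_response(gen, lf)
        assert abs(int(np.argmax(np.diff(pred)))
                   - int(np.argmax(np.diff(true_curve)))) <= 1

    def test_degenerate_data_rejected(self):
        lf = np.linspace(0, 0.5, 8)
        with pytest.raises(ValueError, match="variance"):
            fit_dose_response_model([(lf, np.full(8, 0.3))],
                                    "negative_regulation")

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="dose points"):
            fit_dose_response_model([([0.1, 0.2], [0.1, 0.2])],
                                    "negative_regulation")


class TestSelectModel:
    def _fit_like(self, topo, aic_val, k, checksum="x"):
        from egfrptp.inference import FitResult

        return FitResult(params={}, ci={}, rss=1.0, loglik=0.0, aic=aic_val,
                         n_params=k, n_obs=10, topology=topo,
                         data_checksum=checksum)

    def test_tie_broken_toward_fewer_parameters(self):
        fits = {"a": self._fit_like("a", 10.0, 3),
                "b": self._fit_like("b", 10.0, 2)}
        winner, delta = select_model(fits)
        assert winner == "b"
        assert delta == {"a": 0.0, "b": 0.0}

    def test_delta_table_min_zero(self):
        fits = {"a": self._fit_like("a", 12.0, 3),
                "b": self._fit_like("b", 10.0, 3)}
        _, delta = select_model(fits)
        assert delta["b"] == 0.0
        assert delta["a"] == pytest.approx(2.0)

    def test_different_data_rejected(self):
        fits = {"a": self._fit_like("a", 10.0, 3, "x"),
                "b": self._fit_like("b", 11.0, 3, "y")}
        with pytest.raises(ValueError, match="different data"):
            select_model(fits)

    def test_extra_parameter_penalised_on_null_data(self):
        # negative-regulation truth: the larger nested model must usually
        # lose by the AIC parameter penalty
        gen = ReactionParams(k3=0.0, k4=0.0, topology="negative_regulation")
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            cfg = CohortConfig(n_cells=15, params=gen, noise_sd=0.05,
                               param_cv=0.1, depletion_molar=2e-9,
                               seed=900 + rep)
            cells, _ = synth_dose_response_cells(cfg)
            f_nr = fit_dose_response_model(cells, "negative_regulation",
                                           seed=rep, n_starts=2)
            f_dn = fit_dose_response_model(cells, "double_negative",
                                           seed=rep, n_starts=2)
            wins += f_dn.aic > f_nr.aic
        assert wins >= n_rep - 2


class TestBindingFit:
    def test_noiseless_recovery_exact(self):
        doses = ng_ml_to_molar(DOSE_SERIES_NG_ML)
        m = BindingModel(K_D=DEFAULT_KD_MOLAR, depletion_molar=1e-10)
        y = bound_fraction_depletion(doses, m)
        fit = fit_binding_kd(doses, y, depletion_molar=1e-10)
        assert fit.params["K_D"] == pytest.approx(DEFAULT_KD_MOLAR, rel=1e-6)

    def test_noisy_cohort_recovers_kd_within_reported_bounds(self):
        rng = np.random.default_rng(6)
        doses = ng_ml_to_molar(DOSE_SERIES_NG_ML)
        m = BindingModel(K_D=DEFAULT_KD_MOLAR, depletion_molar=1e-10)
        base = bound_fraction_depletion(doses, m)
        xs, ys = [], []
        for _ in range(20):
            xs.append(doses)
            ys.append(base * (1 + rng.normal(0, 0.10, doses.size)))
        fit = fit_binding_kd(np.concatenate(xs), np.concatenate(ys),
                             depletion_molar=1e-10)
        kd_pm = fit.params["K_D"] * 1e12
        assert 427 <= kd_pm <= 1097
        lo, hi = fit.ci["K_D"]
        assert lo <= DEFAULT_KD_MOLAR <= hi

    def test_zero_depletion_agrees_with_dedicated_hyperbolic_fitter(self):
        rng = np.random.default_rng(7)
        doses = ng_ml_to_molar(DOSE_SERIES_NG_ML)
        y = doses / (doses + DEFAULT_KD_MOLAR) \
            + rng.normal(0, 0.02, doses.size)
        fit = fit_binding_kd(doses, y, depletion_molar=0.0)
        popt, _ = curve_fit(lambda d, kd: d / (d + kd), doses, y,
                            p0=[1e-9], maxfev=10000)
        assert fit.params["K_D"] == pytest.approx(popt[0], rel=1e-8)


class TestRecyclingFit:
    def test_noiseless_exact_recovery(self):
        traces, _ = synth_recycling_traces(k_in=0.31, k_rec=0.23, f0=0.2,
                                           noise_sd=0.0, n_traces=3)
        fit = fit_recycling(traces)
        assert fit["k_in"] == pytest.approx(0.31, abs=1e-6)
        assert fit["k_rec"] == pytest.approx(0.23, abs=1e-6)

    def test_steady_state_fraction_consistent_with_rates(self):
        traces, _ = synth_recycling_traces(noise_sd=0.0, n_traces=2)
        fit = fit_recycling(traces)
        for row in fit["per_trace"]:
            assert row["pm_fraction_ss"] == pytest.approx(
                row["k_rec"] / (row["k_rec"] + row["k_in"]))

    def test_noisy_cohort_recovery_within_15_percent(self):
        traces, _ = synth_recycling_traces(k_in=0.31, k_rec=0.23, f0=0.2,
                                           noise_sd=0.05 * 0.43,
                                           n_traces=14, seed=8)
        fit = fit_recycling(traces)
        assert fit["k_in"] == pytest.approx(0.31, rel=0.15)
        assert fit["k_rec"] == pytest.approx(0.23, rel=0.15)

    def test_flat_trace_rejected(self):
        t = np.arange(5.0, 20.0)
        with pytest.raises(ValueError, match="flat"):
            fit_recycling([(t, np.full(t.size, 0.4))])


class TestSpecificActivity:
    def test_noiseless_exponential_activity(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 3, 120)
        alpha = 0.1 + 0.5 * np.exp(-2.0 * x)
        ctrl = np.full(60, 0.6)
        fit = fit_specific_activity(alpha, x, ctrl + rng.normal(0, 1e-3, 60))
        assert fit.gate == "exponential"
        assert fit.activity == pytest.approx(1.0, rel=0.05)

    def test_identical_to_control_gates_null(self):
        rng = np.random.default_rng(10)
        ctrl = rng.normal(0.5, 0.05, 80)
        fit = fit_specific_activity(ctrl.copy(), rng.uniform(0, 3, 80), ctrl)
        assert fit.gate == "null"
        assert fit.activity == 0.0

    def test_noisy_recovery_within_20_percent_most_replicates(self):
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            rng = np.random.default_rng(200 + rep)
            x = rng.uniform(0, 3, 150)
            alpha = 0.1 + 0.5 * np.exp(-2.0 * x) \
                + rng.normal(0, 0.03, 150)
            ctrl = 0.6 + rng.normal(0, 0.03, 60)
            fit = fit_specific_activity(alpha, x, ctrl)
            if abs(fit.activity - 1.0) < 0.2:
                hits += 1
        assert hits >= round(0.75 * n_rep)


class TestMadOutliers:
    def test_single_outlier_removed(self):
        assert np.array_equal(remove_outliers_mad([1.0, 1.0, 1.0, 100.0]),
                              [1.0, 1.0, 1.0])

    def test_degenerate_mad_keeps_all(self):
        vals = np.full(6, 2.5)
        assert np.array_equal(remove_outliers_mad(vals), vals)

    def test_normal_sample_mostly_retained(self):
        rng = np.random.default_rng(11)
        kept_fracs = []
        for _ in range(30):
            v = rng.normal(0, 1, 200)
            kept_fracs.append(remove_outliers_mad(v, k=3).size / v.size)
        assert np.mean(kept_fracs) >= 0.95

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers_mad([1.0, 2.0])
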