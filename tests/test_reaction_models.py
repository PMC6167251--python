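"""Unit and property tests for the EGFR-PTP reaction models."""

import numpy as np
import pytest

from egfrptp.reaction_models import (
    DEFAULT_NEGATIVE_REGULATION,
    ExtendedParams,
    NetworkState,
    PiecewiseConstantInput,
    PulseProtocol,
    ReactionParams,
    Topology,
    Trajectory,
    ptpe_activity,
    regime_preset,
    rhs_extended,
    rhs_generalized,
    simulate_pulse_train,
    simulate_timecourse,
    steady_state,
    steady_state_extended,
    steady_states_reduced,
    pegfr_dose_response,
)

from conftest import oracle_steady_state_multiplicity, oracle_steady_state_values


def hand_coded_rhs(state, p, L):
    """Mass-balance equations written out independently for the oracle."""
    ep, eep, pa = state
    ligandless_free = p.egfr_total - L - ep
    kinase = (p.alpha1 * ligandless_free + p.alpha2 * ep + p.alpha3 * eep)
    if p.gamma == 0:
        ptpe = p.ptpe_c + 1.0 / (p.ptpe_a + p.ptpe_b * (2 * eep + ep))
    else:
        ptpe = 0.0
    dephos = p.gamma * pa + ptpe
    d_ep = ligandless_free * kinase - ep * dephos
    d_eep = p.k5 * (L / 2 - eep) - eep * dephos
    d_pa = (p.k1 * (p.ptp_total - pa) - p.k2 * pa
            - p.k3 * pa * (2 * eep + ep)
            + p.k4 * (p.ptp_total - pa) * (2 * eep + ep))
    return np.array([d_ep, d_eep, d_pa])


class TestParams:
    def test_topology_restrictions_enforced(self):
        with pytest.raises(ValueError):
            ReactionParams(k3=0.0, topology="double_negative")
        with pytest.raises(ValueError):
            ReactionParams(k3=1.0, k4=1.0, topology="negative_feedback")
        with pytest.raises(ValueError):
            ReactionParams(k3=1.0, topology="negative_regulation")

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ReactionParams(alpha1=-0.1)

    def test_liganded_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            ReactionParams(egf_egfr_total=1.5, egfr_total=1.0)

    def test_gamma_convention(self):
        assert not ReactionParams(gamma=1.0).ptpe_active
        assert ReactionParams(gamma=0.0).ptpe_active

    def test_extended_epsilon_positive(self):
        with pytest.raises(ValueError):
            ExtendedParams(base=ReactionParams(), epsilon=0.0)


class TestPtpeActivity:
    @pytest.mark.parametrize("ep,eep,a,b,c,expected", [
        (0.7, 0.1, 2.0, 0.0, 0.0, 0.5),     # b=0: no phospho dependence
        (0.0, 0.0, 1.0, 1.0, 0.0, 1.0),
        (0.3, 0.2, 1.0, 1.0, 0.2, 0.2 + 1.0 / 1.7),
    ])
    def test_values(self, ep, eep, a, b, c, expected):
        assert ptpe_activity(ep, eep, a, b, c) == pytest.approx(expected)

    def test_asymptote_is_offset(self):
        # activity decays to c as total phosphorylation grows
        assert ptpe_activity(1e9, 1e9, 1.0, 1.0, 0.2) == pytest.approx(
            0.2, abs=1e-8)

    def test_strictly_decreasing_in_phosphorylation(self):
        vals = [ptpe_activity(x, 0.0, 1.0, 2.0, 0.1)
                for x in np.linspace(0, 1, 20)]
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            ptpe_activity(1.0, 1.0, 0.0, 0.0, 0.0)


class TestRhs:
    def test_no_substrate_no_drive_is_stationary(self):
        p = ReactionParams(alpha1=0.0, k5=3.0, egf_egfr_total=0.0)
        d = rhs_generalized(NetworkState(0.0, 0.0, 0.5), p)
        assert d.egfr_p == 0.0
        assert d.egf_egfr_p == 0.0

    def test_exhausted_substrate_only_dephosphorylates(self):
        p = ReactionParams(egf_egfr_total=0.2)
        st = NetworkState(p.egfr_total - p.egf_egfr_total, 0.05, 0.5)
        assert rhs_generalized(st, p).egfr_p <= 0.0

    @pytest.mark.parametrize("gamma,ptpe_b", [(1.0, 0.0), (0.0, 0.5)])
    def test_matches_hand_coded_oracle(self, gamma, ptpe_b):
        p = ReactionParams(alpha1=0.02, alpha2=0.7, alpha3=1.3, gamma=gamma,
                           k1=0.9, k2=0.4, k3=2.5, k5=1.7,
                           egf_egfr_total=0.3, ptp_total=1.4,
                           ptpe_a=1.2, ptpe_b=ptpe_b, ptpe_c=0.1)
        st = NetworkState(0.25, 0.08, 0.6)
        got = rhs_generalized(st, p)
        want = hand_coded_rhs([0.25, 0.08, 0.6], p, 0.3)
        assert np.allclose([got.egfr_p, got.egf_egfr_p, got.ptp_a], want,
                           atol=1e-9)

    def test_out_of_bounds_state_rejected(self):
        p = ReactionParams()
        with pytest.raises(ValueError):
            rhs_generalized(NetworkState(1.5, 0.0, 0.5), p)

    def test_extended_matches_finite_difference_of_added_terms(self):
        ext = ExtendedParams(base=ReactionParams(egf_egfr_total=0.2),
                             gamma1=0.7, k4_star=11.0, k2_star=3.0,
                             epsilon=0.02)
        st = NetworkState(0.3, 0.05, 0.6, 0.4)
        got = rhs_extended(st, ext)
        base = hand_coded_rhs([0.3, 0.05, 0.6], ext.base, 0.2)
        assert got.egfr_p == pytest.approx(base[0] - 0.3 * 0.7 * 0.4,
                                           abs=1e-12)
        assert got.egf_egfr_p == pytest.approx(base[1] - 0.05 * 0.7 * 0.4,
                                               abs=1e-12)
        want_pn = 0.02 * (11.0 * 0.3 * (1.0 - 0.4) - 3.0 * 0.4)
        assert got.ptpn2_a == pytest.approx(want_pn, abs=1e-12)

    def test_extended_ptpn2_decays_without_monomer_phospho(self):
        ext = ExtendedParams(base=ReactionParams())
        d = rhs_extended(NetworkState(0.0, 0.0, 0.5, 0.3), ext)
        assert d.ptpn2_a == pytest.approx(
            -ext.epsilon * ext.k2_star * 0.3)
        assert d.ptpn2_a <= 0

    def test_dimer_flag_disables_dimer_dephosphorylation(self):
        base = ReactionParams(egf_egfr_total=0.2)
        on = ExtendedParams(base=base, ptpn2_acts_on_dimer=True)
        off = ExtendedParams(base=base, ptpn2_acts_on_dimer=False)
        st = NetworkState(0.1, 0.05, 0.5, 0.5)
        assert (rhs_extended(st, off).egf_egfr_p
                > rhs_extended(st, on).egf_egfr_p)


class TestSteadyState:
    def test_negative_regulation_ptp_closed_form(self):
        p = DEFAULT_NEGATIVE_REGULATION
        for fp in steady_state(p, 0.1):
            assert fp.state.ptp_a == pytest.approx(
                p.k1 * p.ptp_total / (p.k1 + p.k2), abs=1e-9)

    def test_no_drive_unique_zero_fixed_point(self):
        p = ReactionParams(alpha1=0.0, alpha2=0.0, alpha3=0.0)
        fps = steady_state(p, 0.0)
        assert len(fps) == 1
        assert fps[0].state.egfr_p == pytest.approx(0.0, abs=1e-9)
        assert fps[0].stability == "stable"

    def test_bistable_multiplicity_matches_scan_oracle(self, toggle_params):
        fps = steady_state(toggle_params, 0.05)
        assert len(fps) == 3
        assert sorted(fp.stability for fp in fps) == [
            "stable", "stable", "unstable"]
        want = oracle_steady_state_values(toggle_params, 0.05)
        got = np.sort([fp.pegfr for fp in fps])
        assert np.allclose(got, want, atol=1e-6)

    def test_reduced_solver_agrees_with_multistart(self, toggle_params):
        for lig in (0.0, 0.05, 0.2):
            red = steady_states_reduced(toggle_params, lig)
            full = steady_state(toggle_params, lig)
            assert len(red) == len(full)
            assert np.allclose(
                sorted(s.egfr_p for s in red),
                sorted(f.state.egfr_p for f in full), atol=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_multiplicity_oracle_equivalence_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        p = ReactionParams(alpha1=10 ** rng.uniform(-3, -1),
                           alpha2=10 ** rng.uniform(-1, 0.7),
                           alpha3=10 ** rng.uniform(-1, 0.7),
                           k2=10 ** rng.uniform(-1.5, 0.5),
                           k3=10 ** rng.uniform(0, 1),
                           k5=10 ** rng.uniform(-0.5, 0.7),
                           ptp_total=rng.uniform(0.5, 3.0))
        lig = rng.uniform(0.0, 0.5)
        assert len(steady_states_reduced(p, lig)) == \
            oracle_steady_state_multiplicity(p, lig)

    def test_topology_decoupling_without_coupling_terms(self):
        # with k3=k4=0 and gamma=0 the phospho subsystem ignores ptp_a
        p = ReactionParams(gamma=0.0, k3=0.0, k4=0.0,
                           topology="negative_regulation",
                           ptpe_a=2.0, ptpe_b=1.0, egf_egfr_total=0.2)
        d1 = rhs_generalized(NetworkState(0.2, 0.05, 0.1), p)
        d2 = rhs_generalized(NetworkState(0.2, 0.05, 0.9), p)
        assert d1.egfr_p == d2.egfr_p
        assert d1.egf_egfr_p == d2.egf_egfr_p


class TestSimulation:
    def test_fixed_point_stays_flat(self, toggle_params):
        fp = steady_state(toggle_params, 0.0)[0]
        traj = simulate_timecourse(toggle_params, fp.state, 0.0,
                                   np.linspace(0, 100, 21))
        assert np.max(np.abs(traj.pegfr - fp.pegfr)) < 1e-6

    def test_step_input_converges_to_steady_state(self, toggle_params):
        p = toggle_params
        init = NetworkState(0.0, 0.0, p.ptp_total * p.k1 / (p.k1 + p.k2))
        traj = simulate_timecourse(p, init, 0.2, np.linspace(0, 300, 31))
        stable = [f for f in steady_state(p, 0.2) if f.stability == "stable"]
        assert min(abs(traj.pegfr[-1] - f.pegfr) for f in stable) < 1e-6

    def test_solution_converged_in_tolerance(self, toggle_params):
        p = toggle_params
        init = NetworkState(0.0, 0.0, 1.0)
        t = np.linspace(0, 50, 11)
        a = simulate_timecourse(p, init, 0.1, t, rtol=1e-8, atol=1e-10)
        b = simulate_timecourse(p, init, 0.1, t, rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(a.states[-1] - b.states[-1])) < 1e-6

    def test_mass_conservation_along_trajectory(self, toggle_params):
        p = toggle_params
        init = NetworkState(0.0, 0.0, 1.0)
        traj = simulate_timecourse(p, init, 0.3, np.linspace(0, 120, 61))
        lig = 0.3 * p.egfr_total
        tol = 1e-7
        assert np.all(traj.egfr_p >= -tol)
        assert np.all(traj.egfr_p <= p.egfr_total - lig + tol)
        assert np.all(traj.egf_egfr_p >= -tol)
        assert np.all(traj.egf_egfr_p <= lig / 2 + tol)
        assert np.all(traj.ptp_a >= -tol)
        assert np.all(traj.ptp_a <= p.ptp_total + tol)

    @pytest.mark.parametrize("topology,kw", [
        ("double_negative", {}),
        ("negative_feedback", {"k3": 0.0, "k4": 4.0}),
        ("negative_regulation", {"k3": 0.0, "k4": 0.0}),
    ])
    def test_long_time_limit_is_a_steady_state(self, topology, kw):
        rng = np.random.default_rng(42)
        for _ in range(5):
            p = ReactionParams(alpha2=10 ** rng.uniform(-0.5, 0.5),
                               alpha3=10 ** rng.uniform(-0.5, 0.5),
                               k2=10 ** rng.uniform(-1, 0.3),
                               ptp_total=rng.uniform(0.8, 2.5),
                               topology=topology, **kw)
            lig = rng.uniform(0, 0.4)
            init = NetworkState(0.0, 0.0, p.ptp_total / 2)
            traj = simulate_timecourse(p, init, lig,
                                       np.linspace(0, 400, 11))
            fps = steady_state(p, lig)
            assert min(abs(traj.pegfr[-1] - f.pegfr) for f in fps) < 1e-6

    def test_piecewise_input_is_honoured(self, toggle_params):
        proto = PiecewiseConstantInput([0.0, 10.0, 20.0], [0.0, 0.3, 0.0])
        init = steady_state(toggle_params, 0.0)[0].state
        traj = simulate_timecourse(toggle_params, init, proto,
                                   np.linspace(0, 30, 31))
        assert traj.inputs[np.searchsorted(traj.times, 15.0)] == 0.3
        assert traj.inputs[-1] == 0.0


class TestDoseResponseSweep:
    def test_forward_backward_differ_only_in_bistable_window(self,
                                                             toggle_params):
        lf = np.linspace(0, 0.15, 61)
        fw = pegfr_dose_response(toggle_params, lf, "forward")
        bw = pegfr_dose_response(toggle_params, lf, "backward")
        differ = np.abs(bw - fw) > 1e-6
        assert differ.any()
        assert np.all(bw[differ] >= fw[differ])
        # outside the window the curves coincide
        assert not differ[0] and not differ[-1]


class TestPulseTrain:
    def test_zero_dose_stays_basal_and_tracks(self):
        ext = regime_preset("tracking")
        proto = PulseProtocol(dose_fraction_liganded=0.0)
        traj, label = simulate_pulse_train(ext, proto)
        assert label == "tracking"
        assert np.ptp(traj.pegfr) < 1e-6

    def test_deep_bistable_regime_stays_trapped(self):
        # phosphorylation remains on the upper branch after the last washout
        ext = regime_preset("trapped")
        traj, label = simulate_pulse_train(ext, PulseProtocol())
        assert label == "trapped"
        basal = steady_state_extended(ext, 0.0)[0].pegfr
        assert traj.pegfr[-1] > 10 * max(basal, 1e-4)

    def test_monostable_regime_returns_to_baseline_between_pulses(self):
        ext = regime_preset("tracking")
        proto = PulseProtocol()
        traj, label = simulate_pulse_train(ext, proto)
        assert label == "tracking"
        fps = steady_state_extended(ext, 0.0)
        baseline = min(fp.pegfr for fp in fps
                       if fp.stability == "stable")
        span = traj.pegfr.max() - baseline
        for k in range(1, proto.n_pulses):
            i = np.searchsorted(traj.times, k * proto.period_minutes - 1e-9) - 1
            assert abs(traj.pegfr[i] - baseline) < 0.05 * span

    def test_biphasic_regime_labelled(self):
        _, label = simulate_pulse_train(regime_preset("biphasic"),
                                        PulseProtocol())
        assert label == "biphasic"


class TestSerialization:
    def test_reaction_params_json_roundtrip(self, tmp_path):
        from egfrptp.reaction_models import params_from_json, params_to_json

        p = ReactionParams(alpha3=0.1, ptp_total=2.3, k3=8.0)
        path = tmp_path / "params.json"
        params_to_json(p, path)
        back = params_from_json(path)
        assert back == p

    def test_extended_params_flat_json_roundtrip(self):
        from egfrptp.reaction_models import params_from_json, params_to_json

        ext = ExtendedParams(base=ReactionParams(ptp_total=1.5), gamma1=0.7)
        back = params_from_json(params_to_json(ext))
        assert isinstance(back, ExtendedParams)
        assert back == ext


class TestTrajectory:
    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 0.0, 1.0], states=np.zeros((3, 3)),
                       inputs=np.zeros(3))

    def test_roundtrip_to_csv(self, tmp_path, toggle_params):
        init = steady_state(toggle_params, 0.0)[0].state
        traj = simulate_timecourse(toggle_params, init, 0.1,
                                   np.linspace(0, 10, 6))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "egfr_p", "egf_egfr_p",
                                    "ptp_a", "ptpn2_a", "input"]
        assert np.allclose(df["egfr_p"], traj.egfr_p)
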