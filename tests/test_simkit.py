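"""Generator-level tests: closed-form oracles, determinism, noise models."""

import numpy as np
import pytest

from myocycle import simkit
from myocycle.simkit import (
    MovieSimConfig,
    RateScheme,
    TrapSimConfig,
    beta_myhc,
    make_adp_competition_transients,
    make_atpase_plate,
    make_dissociation_transients,
    make_motility_movie,
    make_state_trajectory,
    make_trap_trace,
    make_turnover_decay,
    simulate_cycle_dwells,
    simulate_serial_loop,
)


class TestCycleDwells:
    def test_one_state_loop_mean_dwell(self):
        # Exp(2) dwells: mean 0.5 s within 3 standard errors at n = 1e4
        _, dwells = simulate_serial_loop([2.0], n_cycles=10_000, seed=1)
        se = 0.5 / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 0.5) < 3 * se

    def test_mean_cycle_time_matches_analytic(self):
        scheme = beta_myhc()          # serial rates give t_cycle = 1/1.57
        assert scheme.t_cycle == pytest.approx(1 / 1.57)
        states, dwells = simulate_cycle_dwells(scheme, 10_000, seed=2)
        cycles = dwells.reshape(10_000, -1).sum(axis=1)
        se = cycles.std(ddof=1) / np.sqrt(len(cycles))
        assert abs(cycles.mean() - scheme.t_cycle) < 3 * se

    def test_seed_determinism_single_cycle(self):
        a = simulate_cycle_dwells(beta_myhc(), 1, seed=7)
        b = simulate_cycle_dwells(beta_myhc(), 1, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_absorbing_state_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            simulate_serial_loop([1.0, 0.0, 2.0], 10, seed=0)

    def test_scheme_invariants(self):
        with pytest.raises(ValueError):
            RateScheme(p_srx=1.5)
        with pytest.raises(ValueError):
            RateScheme(k_hyd=-1.0)


class TestAtpasePlate:
    def test_half_saturation_identity(self):
        # at [actin] = Km the true well rate is exactly basal + kcat/2
        ds = make_atpase_plate(kcat=0.8, Km=30.0, basal=0.05,
                               actin_concs=[30.0], noise_sd=0.0, seed=0)
        rate = ds.ground_truth["rates_per_well"]["actin_30"]
        assert rate == pytest.approx(0.05 + 0.4, abs=1e-12)

    def test_basal_well_rate_is_basal(self):
        ds = make_atpase_plate(kcat=0.8, Km=30.0, basal=0.03,
                               actin_concs=[10.0], noise_sd=0.0, seed=0)
        assert ds.ground_truth["rates_per_well"]["basal"] == 0.03

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_atpase_plate(0.8, 30.0, 0.03, actin_concs=[-5.0], seed=0)

    def test_standards_are_twofold_dilution(self):
        ds = make_atpase_plate(0.8, 30.0, 0.03, [10.0], noise_sd=0.0, seed=0)
        conc = ds.observables["standards"]["conc_mM"].to_numpy()
        assert np.allclose(conc[:-1] / conc[1:], 2.0)
        assert conc[0] == 1.0 and conc[-1] == pytest.approx(0.0078125)


class TestDissociationTransients:
    def test_kobs_closed_forms(self):
        K1, kp2 = 1 / 80.0, 500.0
        traces = make_dissociation_transients(K1, kp2, [80.0, 1e6],
                                              noise_sd=0.0, seed=0)
        # [ATP] = 1/K1 -> k_obs = k_plus2 / 2 exactly
        assert traces[0].meta["true_kobs"] == pytest.approx(kp2 / 2)
        # [ATP] -> large -> k_obs saturates at k_plus2
        assert traces[1].meta["true_kobs"] == pytest.approx(kp2, rel=1e-4)

    def test_empty_atp_list_rejected(self):
        with pytest.raises(ValueError):
            make_dissociation_transients(0.01, 500.0, [], seed=0)

    def test_seed_determinism(self):
        a = make_dissociation_transients(0.01, 500.0, [10.0], seed=3)
        b = make_dissociation_transients(0.01, 500.0, [10.0], seed=3)
        assert np.array_equal(a[0].signal, b[0].signal)


class TestAdpTransients:
    def test_kobs_closed_forms(self):
        traces = make_adp_competition_transients(
            k0=90.0, K_ADP=17.0, adp_list=[0.0, 17.0], noise_sd=0.0, seed=0)
        assert traces[0].meta["true_kobs"] == 90.0
        assert traces[1].meta["true_kobs"] == pytest.approx(45.0)

    def test_invalid_kadp_rejected(self):
        with pytest.raises(ValueError):
            make_adp_competition_transients(90.0, 0.0, [0.0, 10.0], seed=0)


class TestTurnoverDecay:
    def test_pure_srx_is_single_exponential(self):
        tr = make_turnover_decay(1.0, 0.002, 0.02, noise_sd=0.0, seed=0)
        post = tr.time >= 60.0
        tau = tr.time[post] - 60.0
        assert np.allclose(tr.signal[post], np.exp(-0.002 * tau))

    def test_integral_matches_analytic(self):
        # integral of the noiseless decay = p/k_slow + (1-p)/k_fast
        p, ks, kf = 0.6, 0.004, 0.04
        tr = make_turnover_decay(p, ks, kf, duration_s=5000.0, noise_sd=0.0,
                                 seed=0)
        post = tr.time >= 60.0
        integral = np.trapezoid(tr.signal[post], tr.time[post] - 60.0)
        assert integral == pytest.approx(p / ks + (1 - p) / kf, rel=2e-3)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError, match="ambiguous"):
            make_turnover_decay(0.5, 0.02, 0.02, seed=0)


class TestTrapTrace:
    def test_null_trace_has_no_events(self):
        cfg = TrapSimConfig(event_rate=0.0)
        ds = make_trap_trace(cfg, 2.0, seed=1)
        assert ds.ground_truth["events"] == []

    def test_ou_variance_matches_config(self):
        # stationary variance of the free (event-less) process
        cfg = TrapSimConfig(event_rate=0.0, free_variance=25.0,
                            bound_variance=6.0)
        ds = make_trap_trace(cfg, 10.0, seed=2)
        assert np.var(ds.observables["position_nm"]) == pytest.approx(
            25.0, rel=0.05)

    def test_true_durations_exponential_mean(self):
        cfg = TrapSimConfig(event_rate=3.0, detach_rate=3.7)
        durations = []
        seed = 0
        while len(durations) < 500:
            ds = make_trap_trace(cfg, 200.0, seed=seed)
            durations += [e.duration for e in ds.ground_truth["events"]]
            seed += 1
        d = np.array(durations)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 1 / 3.7) < 3 * se

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="bound_variance"):
            TrapSimConfig(free_variance=10.0, bound_variance=20.0)
        with pytest.raises(ValueError, match="Nyquist"):
            TrapSimConfig(sample_rate=10_000.0, filter_cutoff=10_000.0)


class TestMotilityMovie:
    def test_stationary_filament_midpoints_constant(self):
        cfg = MovieSimConfig(speed=0.0, filament_count=3, frame_count=5,
                             image_shape=(128, 128))
        ds = make_motility_movie(cfg, seed=1)
        mids = ds.ground_truth["midpoints_px"]
        assert np.allclose(mids, mids[:, :1, :])

    def test_midpoint_kinematics(self):
        # 0.5 um/s at 0.1 um/px and 1 s frames = 5 px/frame displacement
        cfg = MovieSimConfig(speed=0.5, pixel_size=0.1, frame_interval=1.0,
                             filament_count=2, frame_count=4,
                             image_shape=(256, 256))
        ds = make_motility_movie(cfg, seed=2)
        mids = ds.ground_truth["midpoints_px"]
        step = np.hypot(*np.diff(mids, axis=1).transpose(2, 0, 1))
        assert np.allclose(step[np.isfinite(step)], 5.0, atol=1e-9)

    def test_leaving_filaments_flagged(self):
        cfg = MovieSimConfig(speed=2.0, pixel_size=0.1, filament_count=8,
                             frame_count=10, image_shape=(64, 64))
        ds = make_motility_movie(cfg, seed=3)
        assert ds.ground_truth["left_field"].any()

    def test_frame_count_minimum(self):
        with pytest.raises(ValueError):
            MovieSimConfig(frame_count=1)


class TestStateTrajectory:
    def test_identity_matrix_constant(self):
        traj = make_state_trajectory(np.eye(3), 100, seed=1)
        assert len(np.unique(traj)) == 1

    def test_stationary_fraction_two_state(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        traj = make_state_trajectory(T, 1_000_000, seed=4)
        frac = np.mean(traj == 0)
        # pi_0 = 2/3; autocorrelation (lambda_2 = 0.7) inflates the SE
        se = np.sqrt(2 / 9 * (1.7 / 0.3) / len(traj))
        assert abs(frac - 2 / 3) < 3 * se

    def test_row_sums_validated(self):
        with pytest.raises(ValueError):
            make_state_trajectory([[0.9, 0.2], [0.2, 0.8]], 10, seed=0)

    def test_seed_determinism(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.array_equal(make_state_trajectory(T, 1000, seed=5),
                              make_state_trajectory(T, 1000, seed=5))


def test_noise_free_limit_round_trips():
    """With zero noise every downstream fit recovers the generator truth."""
    from myocycle import atpase, stopflow, turnover

    ds = make_atpase_plate(0.80, 35.9, 0.03,
                           [10, 15, 20, 30, 45, 60, 80, 100],
                           noise_sd=0.0, seed=1)
    fit, _, _ = atpase.analyze_plate(
        ds.observables["wells"], ds.observables["well_map"],
        ds.observables["standards"], ds.observables["myosin_conc_uM"])
    assert fit.kcat == pytest.approx(0.80, rel=1e-3)
    assert fit.Km == pytest.approx(35.9, rel=1e-3)

    traces = make_dissociation_transients(1 / 79.8, 520.7,
                                          [2, 5, 10, 20, 40, 80, 160, 320],
                                          noise_sd=0.0, seed=1)
    pts = [stopflow.fit_transient_exponential(t) for t in traces]
    afit = stopflow.fit_atp_dependence(pts)
    assert afit.k_plus2 == pytest.approx(520.7, rel=1e-3)
    assert afit.invK1 == pytest.approx(79.8, rel=1e-3)

    tr = make_turnover_decay(0.7, 0.002, 0.02, noise_sd=0.0, seed=1)
    tfit = turnover.fit_single_turnover(tr)
    assert tfit.A_slow == pytest.approx(0.7, rel=1e-3)
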