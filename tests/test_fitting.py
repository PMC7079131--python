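"""Clamp-analysis pipeline: peaks, reversal, Boltzmann/kinetic fits, charge."""

import math

import numpy as np
import pandas as pd
import pytest

import navclust as nc
from navclust import fitting as fit
from navclust import simulate as sim
from navclust.model import DecayParams, double_exp_decay
from navclust.traces import Sweep, TraceSet


def _single_sample_traceset(current, c_m):
    t = np.array([0.0, 0.5, 1.0])
    sw = Sweep(voltage=-40.0, time_ms=t, current_pa=np.full(3, current))
    return TraceSet([sw], c_m=c_m, protocol="activation")


class TestPeakExtraction:
    def test_all_zero_sweep_has_zero_peak(self):
        ts = _single_sample_traceset(0.0, 10.0)
        iv = fit.extract_peak_currents(ts, window=(0.0, 1.0))
        assert iv["peak_pa"].iloc[0] == 0.0

    def test_density_is_peak_over_capacitance(self):
        ts = _single_sample_traceset(-800.0, 10.0)
        iv = fit.extract_peak_currents(ts, window=(0.0, 1.0))
        assert iv["density_pa_pf"].iloc[0] == pytest.approx(-80.0)

    def test_noise_free_family_peaks_match_forward_model_maxima(self, quiet_ephys_cfg):
        # oracle: evaluate the m3h forward model on each sweep's own time
        # grid and take the extremum directly
        from navclust.model import hh_m3h_timecourse

        ts, truth = sim.simulate_activation_family(quiet_ephys_cfg)
        iv = fit.extract_peak_currents(ts)
        for sw, (_, row) in zip(ts.sweeps, iv.iterrows()):
            v = row["voltage"]
            sel = sw.time_ms >= 0.3
            i_model = hh_m3h_timecourse(sw.time_ms[sel], truth["states"][v]) \
                * (v - quiet_ephys_cfg.e_na)
            expected = float(i_model[np.argmax(np.abs(i_model))])
            if abs(expected) > 1.0:  # away from reversal, the extremum is the peak
                assert row["peak_pa"] == pytest.approx(expected, rel=1e-9)

    def test_empty_window_raises(self):
        ts = _single_sample_traceset(-1.0, 10.0)
        with pytest.raises(ValueError, match="window"):
            fit.extract_peak_currents(ts, window=(5.0, 6.0))


class TestReversal:
    def test_midpoint_interpolation(self):
        iv = pd.DataFrame({"voltage": [10.0, 15.0, 20.0],
                           "peak_pa": [-30.0, -10.0, 10.0]})
        assert fit.estimate_reversal(iv) == pytest.approx(17.5)

    def test_recovers_generator_reversal_within_one_step(self, quiet_ephys_cfg):
        ts, _ = sim.simulate_activation_family(quiet_ephys_cfg)
        e = fit.estimate_reversal(fit.extract_peak_currents(ts))
        assert abs(e - quiet_ephys_cfg.e_na) < 5.0

    def test_all_inward_raises(self):
        iv = pd.DataFrame({"voltage": [-40.0, -20.0, 0.0],
                           "peak_pa": [-100.0, -200.0, -50.0]})
        with pytest.raises(fit.FitError, match="zero crossing"):
            fit.estimate_reversal(iv)


class TestBoltzmannFit:
    def test_noiseless_inversion(self):
        v = sim.INACTIVATION_PREPULSES
        p = nc.BoltzmannParams(-96.14, 7.17, nc.Sense.INACTIVATION)
        bf = fit.fit_steady_state_boltzmann(v, nc.boltzmann_curve(v, p), nc.Sense.INACTIVATION)
        assert bf.vhalf == pytest.approx(-96.14, abs=1e-6)
        assert bf.k == pytest.approx(7.17, abs=1e-6)
        assert bf.rss < 1e-12

    def test_noisy_recovery_unbiased(self):
        # sigma = 0.02 on G/Gmax over the activation grid, 100 seeds
        v = sim.ACTIVATION_VOLTAGES
        p = nc.BoltzmannParams(-42.62, 7.28, nc.Sense.ACTIVATION)
        clean = nc.boltzmann_curve(v, p)
        errs = []
        for s in range(100):
            y = clean + np.random.default_rng(s).normal(0, 0.02, v.size)
            bf = fit.fit_steady_state_boltzmann(v, y, nc.Sense.ACTIVATION)
            errs.append(bf.vhalf - p.vhalf)
        assert abs(np.mean(errs)) < 0.5

    def test_flat_input_is_degenerate(self):
        with pytest.raises(fit.FitError, match="degenerate"):
            fit.fit_steady_state_boltzmann(np.linspace(-100, 0, 10), np.full(10, 0.5))

    def test_too_few_points(self):
        with pytest.raises(fit.FitError, match=">= 4"):
            fit.fit_steady_state_boltzmann([0, 1, 2], [0.1, 0.5, 0.9])


class TestGatingEndpoints:
    def test_cube_root_of_midpoint(self):
        act = nc.BoltzmannParams(-42.62, 7.28, nc.Sense.ACTIVATION)
        inact = nc.BoltzmannParams(-96.14, 7.17, nc.Sense.INACTIVATION)
        ep = fit.derive_gating_endpoints(act, inact, -120.0, -42.62)
        assert ep["m_inf"] == pytest.approx(0.5 ** (1 / 3), rel=1e-9)

    def test_holding_potential_saturates_gates(self):
        act = nc.BoltzmannParams(-42.62, 7.28, nc.Sense.ACTIVATION)
        inact = nc.BoltzmannParams(-96.14, 7.17, nc.Sense.INACTIVATION)
        ep = fit.derive_gating_endpoints(act, inact, -120.0, -20.0)
        assert ep["m0"] < 0.05 and ep["h0"] > 0.95

    def test_chained_arithmetic_example(self):
        act = nc.BoltzmannParams(-42.62, 7.28, nc.Sense.ACTIVATION)
        inact = nc.BoltzmannParams(-96.14, 7.17, nc.Sense.INACTIVATION)
        ep = fit.derive_gating_endpoints(act, inact, -120.0, -20.0)
        assert ep["m_inf"] == pytest.approx(0.9571864 ** (1 / 3), abs=1e-5)
        assert ep["m_inf"] == pytest.approx(0.98553, abs=1e-4)


class TestHHTimeConstants:
    def test_noise_free_exact_inversion(self, quiet_ephys_cfg):
        cfg = quiet_ephys_cfg
        ts, _ = sim.simulate_activation_family(cfg)
        tab = fit.fit_hh_time_constants(ts, cfg.activation, cfg.inactivation,
                                        cfg.gmax, cfg.e_na)
        ok = tab[tab["ok"]]
        assert len(ok) >= 15
        for _, r in ok.iterrows():
            assert r["tau_m"] == pytest.approx(cfg.tau_m_of_v(r["voltage"]), rel=1e-6)
            assert r["tau_h"] == pytest.approx(cfg.tau_h_of_v(r["voltage"]), rel=1e-6)
            assert r["rss"] < 1e-10  # residual SS negligible vs signal SS

    def test_noisy_recovery_within_ten_percent(self):
        errs_h = []
        for s in range(30):
            cfg = sim.EphysSimConfig(noise_sd=20.0, seed=s)
            ts, _ = sim.simulate_activation_family(cfg)
            one = TraceSet([x for x in ts.sweeps if x.voltage == -30.0],
                           c_m=cfg.c_m, protocol="activation", meta=ts.meta)
            tab = fit.fit_hh_time_constants(one, cfg.activation, cfg.inactivation,
                                            cfg.gmax, cfg.e_na)
            errs_h.append(abs(tab["tau_h"].iloc[0] - cfg.tau_h_of_v(-30.0))
                          / cfg.tau_h_of_v(-30.0))
        assert np.median(errs_h) < 0.10

    def test_sweep_at_reversal_is_flagged(self, quiet_ephys_cfg):
        cfg = quiet_ephys_cfg
        t = np.arange(0, 50, 0.05)
        sw = Sweep(voltage=cfg.e_na, time_ms=t, current_pa=np.zeros_like(t))
        ts = TraceSet([sw], c_m=cfg.c_m, protocol="activation")
        tab = fit.fit_hh_time_constants(ts, cfg.activation, cfg.inactivation,
                                        cfg.gmax, cfg.e_na)
        assert not tab["ok"].iloc[0]


class TestDoubleExpFit:
    def test_noise_free_exact_recovery(self):
        t = np.arange(0, 50, 0.05)
        y = double_exp_decay(t, DecayParams(300.0, 60.0, 1.0, 12.0))
        sw = Sweep(voltage=-30.0, time_ms=t, current_pa=y)
        df = fit.fit_inactivation_double_exp(sw, peak_window=(0.0, 50.0))
        assert df.params.a1 == pytest.approx(300.0, rel=1e-6)
        assert df.params.a2 == pytest.approx(60.0, rel=1e-6)
        assert df.params.tau1 == pytest.approx(1.0, rel=1e-6)
        assert df.params.tau2 == pytest.approx(12.0, rel=1e-6)
        assert df.prefers_double

    def test_mono_exponential_input_prefers_single(self):
        t = np.arange(0, 50, 0.05)
        y = -400.0 * np.exp(-t / 3.0)
        sw = Sweep(voltage=-30.0, time_ms=t, current_pa=y)
        df = fit.fit_inactivation_double_exp(sw, peak_window=(0.0, 50.0))
        # either the slow amplitude collapses or AIC prefers the single fit
        slow_amp = min(df.params.a1, df.params.a2)
        assert slow_amp < 1e-3 * 400.0 or not df.prefers_double

    def test_noisy_tau1_within_fifteen_percent(self, rng):
        t = np.arange(0, 50, 0.05)
        errs = []
        for s in range(30):
            y = double_exp_decay(t, DecayParams(300.0, 60.0, 1.0, 12.0))
            y = y + np.random.default_rng(s).normal(0, 10.0, t.size)
            sw = Sweep(voltage=-30.0, time_ms=t, current_pa=y)
            df = fit.fit_inactivation_double_exp(sw, peak_window=(0.0, 50.0))
            errs.append(abs(df.params.tau1 - 1.0))
        assert np.median(errs) < 0.15


class TestRecoveryFit:
    @pytest.mark.parametrize("tau,t_half", [(7.64, 5.29), (4.28, 2.97)])
    def test_half_time_from_time_constant(self, tau, t_half):
        t = sim.RECOVERY_INTERVALS
        rf = fit.fit_recovery_timecourse(t, 1 - np.exp(-t / tau))
        assert rf.tau == pytest.approx(tau, rel=1e-6)
        assert rf.t_half == pytest.approx(t_half, abs=0.01)  # printed precision

    def test_exact_samples_invert(self):
        t = sim.RECOVERY_INTERVALS
        rf = fit.fit_recovery_timecourse(t, 1 - np.exp(-t / 10.0))
        assert rf.tau == pytest.approx(10.0, rel=1e-9)
        assert rf.t_half == pytest.approx(6.931, abs=1e-3)

    def test_t_half_identity_holds_exactly(self):
        t = sim.RECOVERY_INTERVALS
        for tau in (2.0, 7.64, 30.0):
            rf = fit.fit_recovery_timecourse(t, 1 - np.exp(-t / tau))
            assert rf.t_half == pytest.approx(rf.tau * math.log(2), rel=1e-12)

    def test_too_few_intervals(self):
        with pytest.raises(fit.FitError):
            fit.fit_recovery_timecourse([1, 2, 3], [0.1, 0.2, 0.3])


class TestVoltageShift:
    def test_zero_shift_is_identity(self):
        df = pd.DataFrame({"voltage": [-90.64, -50.0], "value": [1.0, 2.0]})
        out = fit.apply_voltage_shift(df, 0.0)
        pd.testing.assert_frame_equal(out, df)

    def test_inactivation_shift_maps_beta3_onto_control(self):
        # the printed steady-state inactivation midpoints differ by 5.5 mV
        df = pd.DataFrame({"voltage": [-90.64], "value": [0.5]})
        out = fit.apply_voltage_shift(df, -5.5)
        assert out["voltage"].iloc[0] == pytest.approx(-96.14)
        assert out["value"].iloc[0] == 0.5

    def test_round_trip_composition(self):
        arr = np.array([[-60.0, 1.0], [-40.0, 2.0]])
        out = fit.apply_voltage_shift(fit.apply_voltage_shift(arr, 5.5), -5.5)
        np.testing.assert_allclose(out, arr)


class TestEndToEnd:
    def test_full_pipeline_recovers_generator_parameters(self):
        # 10 noisy cells; median fitted parameters stay close to the
        # noise-free limit of each estimator
        acts, ks_a, vhalfs, ks, enas, taus, tms, ths = ([] for _ in range(8))
        for s in range(10):
            cfg = sim.EphysSimConfig(noise_sd=20.0, seed=100 + s)
            act_ts, _ = sim.simulate_activation_family(cfg)
            inact_ts, _ = sim.simulate_inactivation_family(cfg)
            rec_ts, _ = sim.simulate_recovery_family(cfg, tau_rec=7.64)
            res = fit.analyze_condition(act_ts, inact_ts, rec_ts)
            acts.append(res.act.vhalf)
            ks_a.append(res.act.k)
            vhalfs.append(res.inact.vhalf)
            ks.append(res.inact.k)
            enas.append(res.e_na_fit)
            taus.append(res.recovery_tau)
            row = res.tau_table[res.tau_table["voltage"] == -30.0].iloc[0]
            tms.append(row["tau_m"])
            ths.append(row["tau_h"])
            assert res.recovery_t_half == pytest.approx(
                res.recovery_tau * math.log(2), rel=1e-9)
        assert abs(np.median(acts) - (-42.62)) < 1.0
        assert abs(np.median(ks_a) - 7.28) < 0.5
        assert abs(np.median(vhalfs) - (-96.14)) < 1.0
        assert abs(np.median(ks) - 7.17) < 0.5
        assert abs(np.median(enas) - 19.58) < 2.5
        assert abs(np.median(taus) - 7.64) < 0.5
        assert np.median(tms) == pytest.approx(cfg.tau_m_of_v(-30.0), rel=0.10)
        assert np.median(ths) == pytest.approx(cfg.tau_h_of_v(-30.0), rel=0.10)
        # gating charge from the fitted slope lands in the 3-4 range
        z = nc.charge_from_slope(float(np.median(ks)))
        assert 3.0 < z < 4.0
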