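"""Voltage-clamp analysis: QC, corrections, IV, activation fit, exocytosis."""

import numpy as np
import pytest

import ribbonphys as rp
from ribbonphys import vclamp
from ribbonphys.synth.capacitance import CapacitanceRecording, PoolModel
from ribbonphys.synth.currents import CurrentSweep


class TestQC:
    @pytest.mark.parametrize(
        "mode,r_s,leak,rundown,expect_pass",
        [
            ("ruptured", 13.0, -40.0, 0.10, True),
            ("ruptured", 14.5, -40.0, 0.10, False),
            ("ruptured", 13.0, -60.0, 0.10, False),
            ("ruptured", 13.0, -40.0, 0.30, False),
            ("ruptured", 14.0, -50.0, 0.25, True),  # boundary: all inclusive
            ("perforated", 29.0, 29.0, None, True),
            ("perforated", 30.0, 29.0, None, False),  # strict < for perforated
            ("perforated", 29.0, 30.0, None, False),
        ],
    )
    def test_inclusion_rules(self, mode, r_s, leak, rundown, expect_pass):
        qc = vclamp.qc_recording(mode, r_s, leak, rundown)
        assert qc.passed is expect_pass
        if not expect_pass:
            assert qc.reasons

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="rundown_fraction"):
            vclamp.qc_recording("ruptured", 10.0, -20.0, None)


class TestLeakAndLJP:
    def test_pure_leak_cancels(self):
        (proto,) = rp.synth.make_step_protocol(-87, -17, -17, 5, 20)
        model = rp.ChannelModel(g_max=0.0, g_leak=3.0)
        sweep = rp.synth.simulate_current(proto, model, 0.0, 0)
        corr = vclamp.p4_leak_correct(sweep)
        assert np.max(np.abs(corr.current)) < 1e-9

    def test_correction_recovers_channel_only_oracle(self):
        (proto,) = rp.synth.make_step_protocol(-87, -17, -17, 5, 20)
        full = rp.ChannelModel(g_max=4.0, g_leak=3.0)
        channel_only = rp.ChannelModel(g_max=4.0, g_leak=0.0)
        corr = vclamp.p4_leak_correct(rp.synth.simulate_current(proto, full, 0.0, 0))
        oracle = rp.synth.simulate_current(proto, channel_only, 0.0, 0)
        assert np.allclose(corr.current, oracle.current, atol=1e-9)

    def test_zero_amplitude_step_corrects_to_zero(self):
        (proto,) = rp.synth.make_step_protocol(-87, -87, -87, 5, 20)
        sweep = rp.synth.simulate_current(proto, rp.ChannelModel(g_max=0.0, g_leak=3.0), 0.0, 0)
        assert np.max(np.abs(vclamp.p4_leak_correct(sweep).current)) < 1e-9

    def test_missing_leak_sweeps_rejected(self):
        sweep = CurrentSweep(np.arange(3.0), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError, match="leak"):
            vclamp.p4_leak_correct(sweep)

    @pytest.mark.parametrize("command,ljp,expected", [(-70.0, 17.0, -87.0), (80.0, 17.0, 63.0), (5.0, 0.0, 5.0)])
    def test_ljp_offsets(self, command, ljp, expected):
        assert vclamp.ljp_correct([command], ljp)[0] == expected


class TestExtractIV:
    def test_noiseless_iv_matches_closed_form(self, wt_model, noiseless_iv):
        expected = wt_model.channel_current(noiseless_iv.voltages)
        assert np.max(np.abs(noiseless_iv.currents - expected)) < 0.1

    def test_minimum_lies_in_expected_range(self, noiseless_iv):
        v_min = noiseless_iv.voltages[np.argmin(noiseless_iv.currents)]
        assert -20.0 <= v_min <= -10.0
        assert len(noiseless_iv.voltages) == 30

    def test_step_at_reversal_gives_zero(self, wt_model):
        (proto,) = rp.synth.make_step_protocol(-87, wt_model.v_rev, wt_model.v_rev, 5, 20)
        sweep = vclamp.p4_leak_correct(rp.synth.simulate_current(proto, wt_model, 0.0, 0))
        iv = vclamp.extract_iv([sweep])
        assert abs(iv.currents[0]) < 1e-9

    def test_step_shorter_than_window_rejected(self, wt_model):
        (proto,) = rp.synth.make_step_protocol(-87, -17, -17, 5, 3.0)
        sweep = vclamp.p4_leak_correct(rp.synth.simulate_current(proto, wt_model, 0.0, 0))
        with pytest.raises(ValueError, match="window"):
            vclamp.extract_iv([sweep], window_len=5.0)


class TestActivationFit:
    @pytest.mark.parametrize("v_half,k", [(-29.4, 6.92), (-26.6, 6.98)])
    def test_noiseless_recovery(self, v_half, k):
        model = rp.ChannelModel(g_max=4.0, v_half=v_half, k=k, g_leak=2.0)
        protos = rp.synth.make_step_protocol()
        sweeps = [
            vclamp.p4_leak_correct(rp.synth.simulate_current(p, model, 0.0, 0, ljp=17.0))
            for p in protos
        ]
        fit = vclamp.fit_activation(vclamp.extract_iv(sweeps, ljp=17.0))
        assert fit.v_half == pytest.approx(v_half, abs=0.1)
        assert fit.k == pytest.approx(k, abs=0.1)

    def test_noisy_population_recovery_is_unbiased(self):
        # 12 replicate cells with 5 pA current noise: the mean recovered
        # v_half must sit within 2 SEM of the mean simulated truth
        rng = np.random.default_rng(42)
        protos = rp.synth.make_step_protocol()
        truths, recs = [], []
        for _ in range(12):
            vh = rng.normal(-29.4, 2.48)
            model = rp.ChannelModel(g_max=4.0, v_half=vh, g_leak=2.0)
            sweeps = [
                vclamp.p4_leak_correct(rp.synth.simulate_current(p, model, 5.0, rng))
                for p in protos
            ]
            fit = vclamp.fit_activation(vclamp.extract_iv(sweeps))
            truths.append(vh)
            recs.append(fit.v_half)
        recs = np.array(recs)
        sem = recs.std(ddof=1) / np.sqrt(len(recs))
        assert abs(recs.mean() - np.mean(truths)) < 2 * sem

    def test_flat_iv_flagged_degenerate(self):
        iv = vclamp.IVCurve(voltages=np.arange(-80.0, 60.0, 5.0), currents=np.zeros(28))
        with pytest.raises(vclamp.FitError, match="degenerate"):
            vclamp.fit_activation(iv)

    def test_fractional_activation_properties(self, noiseless_iv):
        fit = vclamp.fit_activation(noiseless_iv)
        frac = fit.fractional_activation
        assert np.all(np.diff(frac) >= 0)
        assert np.all((frac >= 0) & (frac <= 1))
        assert fit.open_probability(fit.v_half) == pytest.approx(0.5)
        assert fit.i_max == pytest.approx(210.0, rel=0.02)
        assert fit.i_max_sign == -1


class TestQca:
    def test_constant_current_rectangle(self):
        t = np.arange(0, 100.0, 0.05)
        cur = np.where((t >= 20) & (t <= 70), -200.0, 0.0)
        sweep = CurrentSweep(t, np.zeros_like(t), cur)
        assert vclamp.compute_qca(sweep, (20.0, 70.0)) == pytest.approx(10.0, rel=1e-3)

    def test_zero_current(self):
        t = np.arange(0, 100.0, 0.05)
        sweep = CurrentSweep(t, np.zeros_like(t), np.zeros_like(t))
        assert vclamp.compute_qca(sweep, (20.0, 70.0)) == 0.0

    def test_simulated_pulse_matches_analytic(self, wt_model):
        (proto,) = rp.synth.make_step_protocol(-87, -17, -17, 5, 100)
        sweep = vclamp.p4_leak_correct(rp.synth.simulate_current(proto, wt_model, 0.0, 0))
        q = vclamp.compute_qca(sweep, proto.analysis_window)
        analytic = abs(wt_model.channel_current(-17.0)) * 100.0 / 1000.0
        assert q == pytest.approx(analytic, rel=0.01)

    def test_sample_rate_refinement_invariance(self, wt_model):
        qs = []
        for dt in (0.05, 0.025):
            (proto,) = rp.synth.make_step_protocol(-87, -17, -17, 5, 50, sample_interval=dt)
            sweep = vclamp.p4_leak_correct(rp.synth.simulate_current(proto, wt_model, 0.0, 0))
            qs.append(vclamp.compute_qca(sweep, proto.analysis_window))
        assert abs(qs[1] - qs[0]) / qs[0] < 1e-3

    def test_empty_window_rejected(self):
        t = np.arange(0, 10.0, 0.1)
        sweep = CurrentSweep(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError):
            vclamp.compute_qca(sweep, (5.0, 5.0))


class TestDeltaCm:
    def test_noiseless_step_exact(self):
        t = np.arange(0, 1600.0, 0.5)
        cm = np.where(t < 600.0, 100.0, 110.0)
        rec = CapacitanceRecording(t, cm, np.zeros_like(t), (600.0, 650.0))
        assert vclamp.compute_delta_cm(rec) == pytest.approx(10.0)

    def test_null_case_within_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 1600.0, 0.5)
        cm = 100.0 + rng.normal(0, 3.0, len(t))
        rec = CapacitanceRecording(t, cm, np.zeros_like(t), (600.0, 650.0))
        n = int(400 / 0.5)
        assert abs(vclamp.compute_delta_cm(rec)) < 3 * 3.0 / np.sqrt(n) * np.sqrt(2)

    def test_insufficient_trace_rejected(self):
        t = np.arange(0, 300.0, 0.5)
        rec = CapacitanceRecording(t, np.full_like(t, 100.0), np.zeros_like(t), (100.0, 150.0))
        with pytest.raises(ValueError, match="ms"):
            vclamp.compute_delta_cm(rec)

    def test_recovery_of_pool_truth(self):
        recs = rp.synth.simulate_capacitance_recording(
            [2, 5, 10, 20, 50, 100], noise_sd=3.0, seed=11
        )
        n = int(400 / 0.2)
        sd_est = 3.0 / np.sqrt(n) * np.sqrt(2)  # SD of the two-window difference
        # simultaneous band for six independent comparisons
        for rec in recs:
            meas = vclamp.compute_delta_cm(rec)
            assert abs(meas - rec.truth["delta_cm"]) < 3 * sd_est


class TestExocytosisCurve:
    def test_pure_rrp_has_no_sustained_slope(self):
        pool = PoolModel(rrp_size=20.0, tau_fast=10.0, sustained_rate=0.0)
        pts = [
            vclamp.ExocytosisPoint(d, float(pool.delta_cm(d))) for d in (2, 5, 10, 20, 50, 100)
        ]
        s = vclamp.exocytosis_curve(pts)
        # residual RRP filling between 50 and 100 ms leaves a slope far
        # below any real sustained rate
        assert abs(s.sustained_rate) < 0.01

    def test_sustained_rate_recovered(self):
        pool = PoolModel(rrp_size=15.0, tau_fast=9.0, sustained_rate=0.35)
        pts = [
            vclamp.ExocytosisPoint(d, float(pool.delta_cm(d))) for d in (2, 5, 10, 20, 50, 100)
        ]
        s = vclamp.exocytosis_curve(pts)
        assert s.sustained_rate == pytest.approx(0.35, rel=0.05)

    def test_single_duration_flags_sustained_undefined(self):
        s = vclamp.exocytosis_curve([vclamp.ExocytosisPoint(10.0, 8.0)])
        assert s.sustained_rate is None
        assert s.fast_delta_cm == 8.0

    def test_pool_closed_forms(self):
        pool = PoolModel(rrp_size=20.0, tau_fast=10.0, sustained_rate=0.0)
        assert pool.delta_cm(1e6) == pytest.approx(20.0)
        assert pool.delta_cm(10.0) == pytest.approx(20.0 * (1 - np.exp(-1)))
        jumps = [r.truth["delta_cm"] for r in rp.synth.simulate_capacitance_recording(
            [2, 5, 10, 20, 50, 100], noise_sd=0.0, seed=0)]
        assert np.all(np.diff(jumps) >= 0)


class TestAdmittanceInversion:
    def test_forward_inverse_identity_on_random_circuits(self):
        rng = np.random.default_rng(7)
        omega = 2 * np.pi * 1000.0
        for _ in range(100):
            cm = rng.uniform(2000.0, 20000.0)  # fF
            gm = rng.uniform(0.2, 5.0)  # nS
            gs = rng.uniform(20.0, 120.0)  # nS
            y = vclamp.circuit_admittance(cm, gm, gs, omega)
            g_t = gs * gm / (gs + gm)
            cm_e, gm_e, gs_e = vclamp.estimate_cm_from_admittance(y.real, y.imag, omega, g_t)
            assert abs(cm_e - cm) / cm < 1e-3
            assert abs(gm_e - gm) / gm < 1e-3
            assert abs(gs_e - gs) / gs < 1e-3

    def test_ideal_clamp_limit(self):
        omega = 2 * np.pi * 1000.0
        y = vclamp.circuit_admittance(10000.0, 1.0, 1e7, omega)
        cm_e, _, _ = vclamp.estimate_cm_from_admittance(y.real, y.imag, omega, 1e7 / (1e7 + 1))
        assert cm_e == pytest.approx(y.imag / omega * 1e6, rel=1e-3)

    def test_no_capacitive_component_rejected(self):
        with pytest.raises(ValueError, match="y_imag"):
            vclamp.estimate_cm_from_admittance(5.0, 0.0, 6283.0, 1.0)

    def test_inconsistent_dc_conductance_rejected(self):
        with pytest.raises(ValueError):
            vclamp.estimate_cm_from_admittance(1.0, 2.0, 6283.0, 5.0)
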