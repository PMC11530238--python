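import io

import numpy as np
import pytest

from pocketcons import (
    AnalysisWindows,
    GatingParams,
    Protocol,
    Sweep,
    build_gv,
    build_iv,
    fit_boltzmann,
    inst_fraction,
    leak_subtract,
    normalize_curves,
    parse_sweeps,
    simulate_family,
    simulate_wash,
    sweep_features,
    wash_fraction_remaining,
    write_sweeps,
)
from pocketcons.ephys import WashTimecourse


def _flat_sweep(value, v=160.0, duration=250.0, rate=10.0):
    t = np.arange(int(duration * rate)) / rate
    return Sweep(step_V=v, time=t, current=np.full_like(t, float(value)))


class TestParsing:
    def test_default_protocol_has_14_steps(self):
        p = Protocol()
        assert len(p.step_Vs) == 14
        assert p.step_Vs[0] == -100.0 and p.step_Vs[-1] == 160.0

    def test_round_trip(self, tmp_path, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        path = tmp_path / "fam.csv"
        write_sweeps(fam, path)
        back = parse_sweeps(path, fam.protocol)
        for v in fam.protocol.step_Vs:
            assert np.allclose(back.sweeps[v].current, fam.sweeps[v].current, atol=1e-5)

    def test_missing_column_errors(self, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        buf = io.StringIO()
        write_sweeps(fam, buf)
        text = buf.getvalue().replace("160mV", "161mV")
        with pytest.raises(ValueError, match="160"):
            parse_sweeps(io.StringIO(text), fam.protocol)


class TestLeakSubtraction:
    def test_family_minus_itself_is_zero(self, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        zero = leak_subtract(fam, fam)
        assert all(np.allclose(s.current, 0.0) for s in zero.sweeps.values())

    def test_recovers_channel_from_channel_plus_leak(self):
        proto = Protocol()
        chan = GatingParams(noise_sd=0.5, leak_g=0.0, seed=1)
        both = GatingParams(noise_sd=0.5, leak_g=0.2, g_max=chan.g_max, seed=1)
        leak_only = GatingParams(noise_sd=0.5, leak_g=0.2, g_max=1e-12, seed=2)
        fam_chan, _ = simulate_family(chan, proto)
        fam_both, _ = simulate_family(both, proto)
        fam_leak, _ = simulate_family(leak_only, proto)
        recovered = leak_subtract(fam_both, fam_leak)
        for v in proto.step_Vs:
            resid = recovered.sweeps[v].current - fam_chan.sweeps[v].current
            assert np.max(np.abs(resid)) <= 6 * 0.5 * np.sqrt(3)  # noise bound

    def test_protocol_mismatch_errors(self, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        other = Protocol(step_Vs=(-100.0, 0.0, 100.0))
        fam2, _ = simulate_family(quiet_gating, other)
        with pytest.raises(ValueError):
            leak_subtract(fam, fam2)


class TestSweepFeatures:
    def test_constant_trace(self):
        f = sweep_features(_flat_sweep(100.0))
        assert f.I_inst == pytest.approx(100.0)
        assert f.I_SS == pytest.approx(100.0)
        assert inst_fraction(f) == pytest.approx(1.0)

    def test_two_component_closed_form(self):
        # I(t) = 2 + 3(1 − e^{−t/τ}) with τ = 500 ms ≫ windows
        tau = 500.0
        t = np.arange(2500) / 10.0
        current = 2.0 + 3.0 * (1.0 - np.exp(-np.minimum(t, 200.0) / tau))
        sweep = Sweep(step_V=160.0, time=t, current=current)
        w = AnalysisWindows(noise_floor_sd_mult=0.0)
        f = sweep_features(sweep, w)
        # window-averaged closed forms
        def mean_I(lo, hi):
            ts = t[(t >= lo) & (t < hi)]
            return np.mean(2.0 + 3.0 * (1.0 - np.exp(-ts / tau)))
        assert f.I_inst == pytest.approx(mean_I(2, 5), abs=1e-9)
        assert f.I_SS == pytest.approx(mean_I(190, 200), abs=1e-9)
        assert f.I_inst == pytest.approx(2.0, abs=0.05)
        assert inst_fraction(f) == pytest.approx(
            mean_I(2, 5) / mean_I(190, 200), abs=1e-9
        )

    def test_noise_only_trace_flagged_unreliable(self):
        rng = np.random.default_rng(0)
        t = np.arange(2500) / 10.0
        sweep = Sweep(step_V=160.0, time=t, current=rng.normal(0, 5.0, t.shape))
        f = sweep_features(sweep)
        assert not f.reliable
        with pytest.warns(UserWarning):
            assert np.isnan(inst_fraction(f))

    def test_window_outside_trace_errors(self):
        sweep = _flat_sweep(1.0, duration=100.0)
        with pytest.raises(ValueError):
            sweep_features(sweep, AnalysisWindows(), step_duration=500.0)


class TestInstFraction:
    @pytest.mark.parametrize("tau", [5.0, 20.0, 80.0])
    @pytest.mark.parametrize("share", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_recovers_planted_share_within_window_tolerance(self, tau, share):
        params = GatingParams(
            noise_sd=0.0, leak_g=0.0, inst_share=share, tau_ms=tau, seed=0
        )
        fam, truth = simulate_family(params, Protocol())
        f = sweep_features(fam.sweeps[160.0], AnalysisWindows(noise_floor_sd_mult=0.0))
        got = f.I_inst / f.I_SS if f.I_SS else np.nan
        expected = truth["I_inst_true"][160.0] / truth["I_SS_true"][160.0]
        # window tolerance: the [2,5] ms window sits on the relaxing phase
        tol = (1.0 - expected) * (1.0 - np.exp(-5.0 / tau)) + 0.02
        assert got == pytest.approx(expected, abs=tol)
        assert 0.0 <= got <= 1.0 + 1e-6


class TestCurves:
    def test_normalization_reference_is_exactly_one(self, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        curves = {"Ca500": build_iv(fam)}
        normed = normalize_curves(curves, "Ca500", 160.0)
        assert normed["Ca500"].points[160.0] == 1.0

    def test_scale_invariance_and_idempotence(self, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        iv = build_iv(fam)
        doubled = type(iv)(kind="IV", points={v: 2 * x for v, x in iv.points.items()})
        n1 = normalize_curves({"Ca500": iv}, "Ca500")["Ca500"]
        n2 = normalize_curves({"Ca500": doubled}, "Ca500")["Ca500"]
        assert n1.points == pytest.approx(n2.points)
        again = normalize_curves({"Ca500": n1}, "Ca500")["Ca500"]
        assert again.points == n1.points

    def test_missing_reference_condition_errors(self, quiet_gating):
        fam, _ = simulate_family(quiet_gating, Protocol())
        with pytest.raises(ValueError, match="reference"):
            normalize_curves({"Ca3000": build_iv(fam)}, "Ca500")

    def test_ohmic_channel_gives_flat_ss_gv(self):
        # leak-only conductance: I = g (V − Vrev) exactly
        proto = Protocol()
        params = GatingParams(noise_sd=0.0, leak_g=1.0, g_max=1e-12, seed=0)
        fam, _ = simulate_family(params, proto)
        gv = build_gv(fam, "steady_state", Vrev=0.0)
        vals = gv.values
        assert np.std(vals) / np.mean(vals) <= 0.01
        assert 0.0 in gv.excluded

    def test_tail_gv_matches_planted_boltzmann(self):
        params = GatingParams(noise_sd=0.0, leak_g=0.0, tau_ms=5.0, seed=0)
        fam, truth = simulate_family(params, Protocol())
        gv = build_gv(fam, "tail")
        g = gv.values / np.max(gv.values)
        po = np.array([truth["po_inf"][v] for v in gv.voltages])
        po = po / po.max()
        assert np.max(np.abs(g - po)) <= 0.05

    def test_instantaneous_channel_ss_equals_tail_gv(self):
        # inst_share 1 puts the step at equilibrium immediately; a tail
        # relaxation far slower than the measurement window freezes the
        # step-end conductance, so both G–V sources must coincide
        params = GatingParams(
            noise_sd=0.0, leak_g=0.0, inst_share=1.0, tau_ms=1e9, seed=0
        )
        fam, _ = simulate_family(params, Protocol())
        ss = build_gv(fam, "steady_state", Vrev=0.0)
        tail = build_gv(fam, "tail")
        common = [v for v in ss.points if v in tail.points]
        a = np.array([ss.points[v] for v in common])
        b = np.array([tail.points[v] for v in common])
        assert np.allclose(a / a.max(), b / b.max(), atol=1e-6)

    def test_higher_po_condition_exceeds_reference(self):
        proto = Protocol()
        sub = GatingParams(noise_sd=0.0, leak_g=0.0, g_max=1.0, seed=0)
        sat = GatingParams(noise_sd=0.0, leak_g=0.0, g_max=2.0, seed=0)
        fam_sub, _ = simulate_family(sub, proto)
        fam_sat, _ = simulate_family(sat, proto)
        curves = {"Ca500": build_iv(fam_sub), "Ca3000": build_iv(fam_sat)}
        normed = normalize_curves(curves, "Ca500", 160.0)
        assert normed["Ca3000"].points[160.0] > 1.0


class TestWash:
    def test_constant_trace_fraction_one(self):
        t = np.arange(0.0, 30.0, 0.1)
        tc = WashTimecourse(times=t, currents=np.full_like(t, 500.0), removal_time=5.0)
        assert wash_fraction_remaining(tc) == pytest.approx(1.0)

    def test_exponential_decay_tau7(self):
        t = np.arange(0.0, 30.0, 0.01)
        cur = 400.0 * np.where(t <= 5.0, 1.0, np.exp(-(t - 5.0) / 7.0))
        tc = WashTimecourse(times=t, currents=cur, removal_time=5.0)
        assert wash_fraction_remaining(tc) == pytest.approx(np.exp(-2.0), rel=1e-3)

    def test_slow_unbinding_retains_more_current(self):
        slow, _ = simulate_wash(GatingParams(noise_sd=0.0, unbind_tau_s=12.0))
        fast, _ = simulate_wash(GatingParams(noise_sd=0.0, unbind_tau_s=3.0))
        assert wash_fraction_remaining(slow) > wash_fraction_remaining(fast)

    def test_insufficient_span_errors(self):
        t = np.arange(0.0, 10.0, 0.1)
        tc = WashTimecourse(times=t, currents=np.ones_like(t), removal_time=5.0)
        with pytest.raises(ValueError):
            wash_fraction_remaining(tc)


class TestBoltzmannFit:
    def test_noiseless_recovery_is_exact(self):
        V = np.arange(-100.0, 161.0, 20.0)
        G = 2.0 / (1.0 + np.exp((80.0 - V) / 30.0))
        from pocketcons.ephys import CurveSet

        gv = CurveSet(kind="GV", points=dict(zip(V, G)))
        fit = fit_boltzmann(gv)
        assert fit.converged
        assert fit.V_half == pytest.approx(80.0, abs=0.1)
        assert fit.slope == pytest.approx(30.0, abs=0.1)

    def test_two_percent_noise_within_5mV(self):
        rng = np.random.default_rng(42)
        V = np.arange(-100.0, 161.0, 20.0)
        G = 2.0 / (1.0 + np.exp((80.0 - V) / 30.0))
        G_noisy = G + rng.normal(0.0, 0.02 * G.max(), G.shape)
        from pocketcons.ephys import CurveSet

        fit = fit_boltzmann(CurveSet(kind="GV", points=dict(zip(V, G_noisy))))
        assert fit.converged
        assert fit.V_half == pytest.approx(80.0, abs=5.0)

    def test_flat_curve_flagged(self):
        from pocketcons.ephys import CurveSet

        V = np.arange(-100.0, 161.0, 20.0)
        fit = fit_boltzmann(CurveSet(kind="GV", points={v: 1.0 for v in V}))
        assert not fit.converged
        assert "flat" in fit.message
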