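import numpy as np
import pytest

from ehtkit import mechanics as mech
from ehtkit import synthetic_data as sd
from ehtkit.datatypes import ForceLengthCurve, ForceTrace


def _triangle_train(n=5, freq=1.0, tr=50.0, td=150.0, amplitude=4.0,
                    passive=1.0, dt=0.5):
    cfg = sd.TwitchSimConfig(
        n_twitches=n, stim_frequency=freq, tau_rise=tr, tau_decay=td,
        amplitude=amplitude, passive_offset=passive, dt=dt, shape="triangle",
    )
    return sd.gen_twitch_train(cfg)


class TestSegmentTwitches:
    def test_five_twitches_at_1hz(self):
        trace, _ = _triangle_train(n=5, freq=1.0)
        windows = mech.segment_twitches(trace)
        assert len(windows) == 5
        starts = np.array([trace.time[s] for s, _ in windows])
        assert np.allclose(np.diff(starts), 1000.0, atol=trace.dt)

    def test_flat_trace_empty_with_warning(self):
        trace = ForceTrace(time=np.arange(100.0), force=np.ones(100))
        with pytest.warns(UserWarning):
            assert mech.segment_twitches(trace) == []

    def test_markers_override_detection(self):
        trace, _ = _triangle_train(n=3, freq=1.0)
        n_with = len(mech.segment_twitches(trace))
        trace_nomark = ForceTrace(time=trace.time, force=trace.force)
        n_without = len(mech.segment_twitches(trace_nomark))
        assert n_with == n_without == 3

    def test_detection_without_markers(self):
        trace, _ = _triangle_train(n=4, freq=1.0)
        anon = ForceTrace(time=trace.time, force=trace.force)
        assert len(mech.segment_twitches(anon)) == 4


class TestTwitchMetrics:
    def test_triangle_closed_forms(self):
        trace, truth = _triangle_train(tr=50.0, td=150.0, dt=0.25)
        m = mech.twitch_metrics(trace, window=mech.segment_twitches(trace)[0])
        assert m.rise_time == pytest.approx(0.8 * 50.0, abs=trace.dt)
        assert m.decay_time == pytest.approx(0.8 * 150.0, abs=trace.dt)
        # 10 % up at 0.1*Tr, 10 %-remaining down at Tr + 0.9*Td.
        assert m.total_time == pytest.approx(0.9 * 50.0 + 0.9 * 150.0, abs=trace.dt)

    @pytest.mark.parametrize("tr", [20.0, 50.0, 100.0])
    @pytest.mark.parametrize("td", [100.0, 200.0, 400.0])
    def test_biexp_matches_dense_oracle(self, tr, td):
        if td <= tr:
            with pytest.raises(ValueError):
                sd.TwitchSimConfig(tau_rise=tr, tau_decay=td)
            return
        cfg = sd.TwitchSimConfig(
            tau_rise=tr, tau_decay=td, dt=1.0, n_twitches=2, stim_frequency=0.3
        )
        trace, truth = sd.gen_twitch_train(cfg)
        m = mech.twitch_metrics(trace, window=mech.segment_twitches(trace)[0])
        assert m.rise_time == pytest.approx(truth["rise_time"], abs=trace.dt)
        assert m.decay_time == pytest.approx(truth["decay_time"], abs=trace.dt)
        assert m.total_time == pytest.approx(truth["total_time"], abs=trace.dt)

    def test_amplitude_above_baseline(self):
        trace, _ = _triangle_train(amplitude=4.0, passive=1.0)
        m = mech.twitch_metrics(trace, window=mech.segment_twitches(trace)[0])
        assert m.amplitude == pytest.approx(4.0, rel=1e-6)
        assert m.baseline == pytest.approx(1.0, rel=1e-6)

    def test_offset_invariance_and_scale_equivariance(self):
        trace, _ = _triangle_train()
        w = mech.segment_twitches(trace)[0]
        m0 = mech.twitch_metrics(trace, window=w)

        shifted = ForceTrace(
            time=trace.time, force=trace.force + 2.5, stim_times=trace.stim_times
        )
        m1 = mech.twitch_metrics(shifted, window=w)
        assert m1.amplitude == pytest.approx(m0.amplitude)
        assert m1.rise_time == pytest.approx(m0.rise_time)

        scaled = ForceTrace(
            time=trace.time, force=trace.force * 3.0, stim_times=trace.stim_times
        )
        m2 = mech.twitch_metrics(scaled, window=w)
        assert m2.amplitude == pytest.approx(3.0 * m0.amplitude)
        assert m2.rise_time == pytest.approx(m0.rise_time)
        assert m2.decay_time == pytest.approx(m0.decay_time)

    def test_unrelaxed_twitch_flagged(self):
        t = np.arange(0.0, 300.0, 1.0)
        f = np.clip((t - 100.0) / 50.0, 0.0, 1.0)  # rises, never relaxes
        trace = ForceTrace(time=t, force=f, stim_times=np.array([100.0]))
        m = mech.twitch_metrics(trace)
        assert "decay_undefined" in m.flags
        assert m.total_time is None


class TestForceLength:
    def test_synthetic_affine_curve_recovered(self):
        strains = np.arange(100.0, 121.0, 2.0)
        traces = {}
        for s in strains:
            cfg = sd.TwitchSimConfig(
                n_twitches=3, stim_frequency=1.0, amplitude=4.0,
                passive_offset=0.1 * (s - 100.0), shape="triangle",
                tau_rise=50.0, tau_decay=150.0, dt=1.0,
            )
            traces[s], _ = sd.gen_twitch_train(cfg)
        curve = mech.force_length(traces, csa_mm2=0.3)
        assert curve.strain_pct.size == 11
        assert np.allclose(curve.passive_mN, 0.1 * (strains - 100.0), atol=1e-9)
        assert np.allclose(curve.active_mN, 4.0, rtol=1e-6)

    def test_zero_response_zero_active(self):
        t = np.arange(0.0, 3000.0, 1.0)
        trace = ForceTrace(
            time=t, force=np.full_like(t, 0.5),
            stim_times=np.array([500.0, 1500.0, 2500.0]),
        )
        curve = mech.force_length({100.0: trace, 112.0: trace}, csa_mm2=0.3)
        assert np.allclose(curve.active_mN, 0.0)
        assert np.allclose(curve.passive_mN, 0.5)

    def test_missing_baseline_skipped(self):
        t = np.arange(0.0, 1000.0, 1.0)
        good = ForceTrace(time=t, force=np.ones_like(t), stim_times=np.array([500.0]))
        bad = ForceTrace(time=t, force=np.ones_like(t))  # no markers at all
        with pytest.warns(UserWarning):
            curve = mech.force_length({100.0: good, 102.0: bad}, csa_mm2=0.3)
        assert curve.strain_pct.tolist() == [100.0]


class TestStiffness:
    def _curve(self, passive, strains=None):
        strains = np.arange(100.0, 121.0, 2.0) if strains is None else strains
        return ForceLengthCurve(
            strain_pct=strains,
            passive_mN=passive(strains / 100.0),
            active_mN=np.zeros_like(strains),
            csa_mm2=0.3,
        )

    def test_affine_closed_form(self):
        # passive = 3 * strain_fraction, csa 0.3 -> 3 / 0.3 = 10 kPa.
        curve = self._curve(lambda f: 3.0 * f)
        assert mech.stiffness(curve) == pytest.approx(10.0)

    def test_constant_passive_zero(self):
        curve = self._curve(lambda f: np.full_like(f, 0.7))
        assert mech.stiffness(curve) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_matches_secant_oracle(self):
        fn = lambda f: 0.2 * np.exp(3.0 * (f - 1.0))
        curve = self._curve(fn)
        got = mech.stiffness(curve)
        # Independent oracle: closed-form least squares on the top 3 points.
        x = np.array([1.16, 1.18, 1.20])
        y = fn(x)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert got == pytest.approx(slope / 0.3, rel=1e-9)

    def test_too_few_qualifying_levels_rejected(self):
        curve = self._curve(lambda f: 3.0 * f, strains=np.array([100.0, 104.0, 120.0]))
        with pytest.raises(ValueError):
            mech.stiffness(curve)


class TestScalars:
    def test_specific_force(self):
        assert mech.specific_force(4.0, 0.25) == pytest.approx(16.0)
        assert mech.specific_force(0.0, 0.25) == 0.0
        assert mech.specific_force(4.0, 0.5) == pytest.approx(
            mech.specific_force(4.0, 0.25) / 2
        )

    def test_specific_force_rejects_bad_csa(self):
        with pytest.raises(ValueError):
            mech.specific_force(4.0, 0.0)

    def test_ffr_flat(self):
        res = mech.ffr({1.0: 5.0, 1.5: 5.0, 2.0: 5.0})
        assert np.allclose(res.normalized_pct, 100.0)
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_ffr_published_fractions(self):
        F = 4.0
        res = mech.ffr({1.0: F, 1.5: 0.95 * F, 2.0: 0.83 * F})
        assert np.allclose(res.normalized_pct, [100.0, 95.0, 83.0])
        assert res.slope == pytest.approx(-17.0)

    def test_ffr_requires_1hz(self):
        with pytest.raises(ValueError):
            mech.ffr({1.5: 4.0, 2.0: 3.0})

    def test_force_per_input_cm(self):
        assert mech.force_per_input_cm(5.0, 0.5e6, 1.0) == pytest.approx(10.0)
        assert mech.force_per_input_cm(5.0, 0.5e6, 0.5) == pytest.approx(20.0)
        assert mech.force_per_input_cm(5.2, 0.5e6, 0.863) == pytest.approx(
            12.05, abs=0.005
        )

    def test_force_per_input_cm_rejects(self):
        with pytest.raises(ValueError):
            mech.force_per_input_cm(5.0, 0, 1.0)
        with pytest.raises(ValueError):
            mech.force_per_input_cm(5.0, 1e6, 1.5)
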