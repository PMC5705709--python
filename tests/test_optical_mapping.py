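import numpy as np
import pytest

from ehtkit import optical_mapping as om
from ehtkit import synthetic_data as sd
from ehtkit.datatypes import ActivationMap, ActivityTrace, MovieStack


def _movie_from_traces(traces, dt=1.0, pixel_size=1.0):
    """Stack per-pixel traces (dict {(r, c): 1-D array}) into a movie."""
    rows = max(r for r, _ in traces) + 1
    cols = max(c for _, c in traces) + 1
    n = len(next(iter(traces.values())))
    frames = np.zeros((n, rows, cols))
    for (r, c), tr in traces.items():
        frames[:, r, c] = tr
    return MovieStack(frames=frames, dt=dt, pixel_size=pixel_size)


class TestCondition:
    def test_constant_pixel_removed(self, plane_movie_25):
        movie, _, _ = plane_movie_25
        movie = movie.copy()
        movie.frames[:, 0, 0] = 3.14
        cond = om.condition(movie)
        assert not cond.mask[0, 0]
        assert cond.mask[5, 5]

    def test_noiseless_pixel_normalized_to_unit(self, plane_movie_25):
        movie, _, _ = plane_movie_25
        cond = om.condition(movie)
        trace = cond.frames[:, 10, 10]
        assert trace.min() == pytest.approx(0.0, abs=1e-12)
        assert trace.max() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, plane_movie_25):
        movie, _, _ = plane_movie_25
        scaled = movie.copy()
        scaled.frames = 7.5 * scaled.frames + 42.0
        a = om.condition(movie)
        b = om.condition(scaled)
        assert np.array_equal(a.mask, b.mask)
        assert np.allclose(a.frames[:, a.mask], b.frames[:, b.mask])

    def test_all_removed_raises(self):
        frames = np.ones((10, 4, 4))
        movie = MovieStack(frames=frames, dt=1.0, pixel_size=1.0)
        with pytest.raises(ValueError, match="SNR threshold"):
            om.condition(movie)


class TestActivationMap:
    def test_step_crossing_at_midpoint(self):
        tr = np.concatenate([np.zeros(5), np.ones(10)])  # step between 4 and 5
        movie = _movie_from_traces({(0, 0): tr, (0, 1): tr}, dt=2.0)
        amap = om.activation_map(movie)
        assert amap.act_time[0, 0] == pytest.approx((4 + 0.5) * 2.0)

    def test_plane_wave_matches_truth(self, plane_movie_25):
        movie, truth, _ = plane_movie_25
        cond = om.condition(movie)
        amap = om.activation_map(cond)
        err = np.abs(amap.act_time - truth.act_time)
        assert np.nanmax(err) <= movie.dt / 2

    def test_simultaneous_activation_equal_times(self):
        ap = sd.APTemplate()
        t = np.arange(0, 600.0, 1.0)
        tr = ap(t - 20.0)
        movie = _movie_from_traces({(r, c): tr for r in range(4) for c in range(4)})
        amap = om.activation_map(om.condition(movie))
        vals = amap.act_time[np.isfinite(amap.act_time)]
        assert np.allclose(vals, vals[0])

    def test_no_crossing_is_undefined_with_warning(self):
        ap = sd.APTemplate()
        t = np.arange(0, 600.0, 1.0)
        good = ap(t - 20.0)
        # Oscillating sub-threshold pixel: passes SNR, never crosses 0.5
        # of its own normalized range upward after start.
        frames = np.zeros((t.size, 1, 3))
        for c in range(3):
            frames[:, 0, c] = good
        movie = MovieStack(frames=frames, dt=1.0, pixel_size=1.0)
        cond = om.condition(movie)
        # Two of three pixels start high and only fall: no upward crossing.
        cond.frames[:, 0, 1] = np.linspace(1.0, 0.0, t.size)
        cond.frames[:, 0, 2] = np.linspace(1.0, 0.0, t.size)
        amap = om.activation_map(cond)
        assert np.isnan(amap.act_time[0, 1])
        assert "warning" in amap.meta

    def test_max_dvdt_close_to_half_amplitude(self, plane_movie_25):
        movie, truth, _ = plane_movie_25
        cond = om.condition(movie)
        amap = om.activation_map(cond, method="max_dvdt")
        # Linear upstroke: derivative is flat across the upstroke, so the
        # dV/dt marker may sit anywhere within it.
        err = np.abs(amap.act_time - truth.act_time)
        assert np.nanmax(err) <= sd.APTemplate().upstroke


class TestIsochrones:
    def test_linear_ramp_band_count(self):
        act = np.tile(np.linspace(0.0, 20.0, 10, endpoint=False), (5, 1))
        amap = ActivationMap(act_time=act, pixel_size=1.0)
        bands = om.isochrones(amap, 5.0)
        assert len(np.unique(bands[bands >= 0])) == 4

    def test_uniform_map_single_band(self):
        amap = ActivationMap(act_time=np.full((4, 4), 7.0), pixel_size=1.0)
        bands = om.isochrones(amap, 5.0)
        assert len(np.unique(bands)) == 1

    def test_point_source_bands_grow_with_radius(self, point_movie_40):
        movie, truth, _ = point_movie_40
        bands = om.isochrones(truth, 5.0)
        r, c = np.mgrid[0 : bands.shape[0], 0 : bands.shape[1]]
        radius = np.hypot(r, c)
        order = np.argsort(radius.ravel())
        b = bands.ravel()[order]
        assert np.all(np.diff(np.maximum.accumulate(b)) >= 0)

    def test_rejects_bad_interval(self):
        amap = ActivationMap(act_time=np.zeros((3, 3)), pixel_size=1.0)
        with pytest.raises(ValueError):
            om.isochrones(amap, 0.0)


class TestConductionVelocity:
    def test_exact_plane_closed_form(self):
        # T = x / 0.25 mm/ms -> 25 cm/s.
        x = np.arange(12) * 1.0
        act = np.tile(x / 0.25, (10, 1))
        amap = ActivationMap(act_time=act, pixel_size=1.0)
        res = om.conduction_velocity(amap, method="local_plane")
        assert res.mean_cv == pytest.approx(25.0, rel=1e-9)

    def test_exact_radial_closed_form(self):
        r, c = np.mgrid[0:20, 0:20]
        act = np.hypot(r, c) * 1.0 / 0.25
        amap = ActivationMap(act_time=act, pixel_size=1.0, stimulus_rc=(0, 0))
        res = om.conduction_velocity(amap, method="radial_fit")
        assert res.mean_cv == pytest.approx(25.0, rel=1e-9)

    def test_point_source_recovery_within_2pct(self, point_movie_40):
        movie, truth, _ = point_movie_40
        cond = om.condition(movie)
        amap = om.activation_map(cond, stimulus_rc=(0, 0))
        res = om.conduction_velocity(amap)
        assert res.mean_cv == pytest.approx(40.0, rel=0.02)

    def test_methods_agree_on_point_source(self, point_movie_40):
        movie, truth, _ = point_movie_40
        cond = om.condition(movie)
        amap = om.activation_map(cond, stimulus_rc=(0, 0))
        a = om.conduction_velocity(amap, method="local_plane").mean_cv
        b = om.conduction_velocity(amap, method="radial_fit").mean_cv
        assert abs(a - b) / b <= 0.05

    def test_uniform_map_unresolvable(self):
        amap = ActivationMap(act_time=np.full((8, 8), 5.0), pixel_size=1.0)
        with pytest.raises(ValueError, match="no resolvable propagation"):
            om.conduction_velocity(amap)

    def test_mean_equals_mean_of_speed_map(self, point_movie_40):
        movie, truth, _ = point_movie_40
        amap = om.activation_map(om.condition(movie), stimulus_rc=(0, 0))
        res = om.conduction_velocity(amap)
        assert res.mean_cv == pytest.approx(np.nanmean(res.speed_map))
        assert res.n_pixels == int(np.isfinite(res.speed_map).sum())


class TestAPDMap:
    def test_template_closed_form_460(self):
        # Instantaneous upstroke, 300 ms plateau, 200 ms linear ramp.
        ap = sd.APTemplate(upstroke=0.0, plateau=300.0, repol=200.0)
        t = np.arange(0.0, 700.0, 1.0)
        tr = ap(t - 50.0)
        movie = _movie_from_traces({(r, c): tr for r in range(3) for c in range(3)})
        cond = om.condition(movie)
        amap = om.activation_map(cond)
        apd = om.apd_map(cond, amap)
        assert np.nanmedian(apd.apd) == pytest.approx(460.0, abs=movie.dt)

    def test_square_pulse_duration(self):
        D = 200.0
        t = np.arange(0.0, 500.0, 1.0)
        tr = ((t >= 100.0) & (t < 100.0 + D)).astype(float)
        movie = _movie_from_traces({(0, 0): tr, (0, 1): tr})
        cond = om.condition(movie)
        amap = om.activation_map(cond)
        apd = om.apd_map(cond, amap)
        assert apd.apd[0, 0] == pytest.approx(D, abs=movie.dt)

    def test_generator_truth(self, plane_movie_25):
        movie, truth, apd_truth = plane_movie_25
        cond = om.condition(movie)
        amap = om.activation_map(cond)
        apd = om.apd_map(cond, amap)
        assert np.nanmedian(apd.apd) == pytest.approx(apd_truth, abs=movie.dt)

    def test_no_repolarization_undefined(self):
        t = np.arange(0.0, 300.0, 1.0)
        rises = np.clip(t / 50.0, 0, 1)  # never comes back down
        movie = _movie_from_traces({(0, 0): rises, (0, 1): rises})
        cond = om.condition(movie)
        amap = om.activation_map(cond)
        apd = om.apd_map(cond, amap)
        assert np.isnan(apd.apd[0, 0])


class TestBurstProtocol:
    def test_nine_episodes(self):
        assert len(om.burst_protocol()) == 9

    def test_endpoints(self):
        p = om.burst_protocol()
        assert p[0] == 2 and p[-1] == 20

    def test_two_hz_steps_from_six(self):
        p = om.burst_protocol()
        assert np.all(np.diff(p[1:]) == 2)


class TestClassifyEpisode:
    def test_none(self):
        tr = sd.gen_arrhythmia_episode("none", 0.0)
        assert om.classify_episode(tr).verdict == "none"

    def test_unsustained_30s(self):
        tr = sd.gen_arrhythmia_episode("unsustained", 30.0)
        res = om.classify_episode(tr)
        assert res.verdict == "unsustained"
        assert res.ectopic_duration_s == pytest.approx(30.0, abs=0.02)

    def test_sustained_70s(self):
        tr = sd.gen_arrhythmia_episode("sustained", 70.0)
        assert om.classify_episode(tr).verdict == "sustained"

    def test_offset_outside_record_rejected(self):
        tr = ActivityTrace(time_s=np.arange(100) * 0.1, value=np.zeros(100))
        with pytest.raises(ValueError):
            om.classify_episode(tr, pacing_offset_s=50.0)

    def test_short_record_flags_capped(self):
        tr = sd.gen_arrhythmia_episode("unsustained", 30.0)
        keep = tr.time_s <= tr.pacing_offset_s + 20.0  # truncate at 20 s
        short = ActivityTrace(
            time_s=tr.time_s[keep], value=tr.value[keep],
            pacing_offset_s=tr.pacing_offset_s,
        )
        res = om.classify_episode(short)
        assert res.capped


class TestAssessCoupling:
    def test_identical_events_coupled(self):
        ev = [10.0, 500.0, 1000.0]
        res = om.assess_coupling(ev, ev)
        assert res["fraction"] == 1.0
        assert res["verdict"] == "coupled"

    def test_silent_graft_uncoupled(self):
        res = om.assess_coupling([10.0, 500.0], [])
        assert res["fraction"] == 0.0
        assert res["verdict"] == "uncoupled"

    def test_fixed_lag_within_window(self):
        host = np.arange(10) * 500.0
        graft = host + 20.0
        res = om.assess_coupling(host, graft, latency_window=50.0)
        assert res["fraction"] == 1.0
        assert np.allclose(res["latencies"], 20.0)

    def test_empty_host_rejected(self):
        with pytest.raises(ValueError):
            om.assess_coupling([], [1.0])


class TestTimeShiftEquivariance:
    def test_delay_shifts_activation_only(self, plane_movie_25):
        movie, _, _ = plane_movie_25
        n_delay = 24
        delayed = movie.copy()
        pad = np.repeat(movie.frames[:1], n_delay, axis=0)
        delayed.frames = np.concatenate([pad, movie.frames], axis=0)

        a0 = om.activation_map(om.condition(movie))
        a1 = om.activation_map(om.condition(delayed))
        shift = n_delay * movie.dt
        assert np.allclose(a1.act_time - a0.act_time, shift, atol=1e-6)

        cv0 = om.conduction_velocity(a0).mean_cv
        cv1 = om.conduction_velocity(a1).mean_cv
        assert cv1 == pytest.approx(cv0, rel=1e-9)
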