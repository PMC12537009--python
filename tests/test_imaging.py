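"""Hotspot-movie generation and the dF/F0 fluorescence-voltage pipeline."""

import numpy as np
import pytest

import ribbonphys as rp
from ribbonphys import imaging
from conftest import run_fv_pipeline


@pytest.fixture(scope="module")
def null_movie(ramp_pair):
    """Movie with silent channels: frames are statistically baseline."""
    model = rp.ChannelModel(g_max=0.0)
    return rp.synth.simulate_hotspot_movie(ramp_pair, model, noise_sd=2.0, seed=5)


class TestGenerator:
    def test_seed_determinism(self, ramp_pair):
        m = rp.ChannelModel(g_max=4.0)
        a = rp.synth.simulate_hotspot_movie(ramp_pair, m, seed=9)
        b = rp.synth.simulate_hotspot_movie(ramp_pair, m, seed=9)
        assert np.array_equal(a.frames_a, b.frames_a)
        assert np.array_equal(a.frames_b, b.frames_b)

    def test_null_movie_delta_f_is_noise(self, null_movie):
        img = imaging.delta_f_image(null_movie)
        sd = img.std()
        assert abs(img.mean()) < 3 * sd / np.sqrt(img.size)
        # isolated false positives beyond 5 noise SD are essentially absent
        assert (np.abs(img) > 5 * sd).sum() <= 2

    def test_indicator_saturation_at_center(self, ramp_pair):
        mov = rp.synth.simulate_hotspot_movie(
            ramp_pair, rp.ChannelModel(g_max=4.0), bg_offset=0.0, noise_sd=0.0,
            c_scale=1e9, seed=0,
        )
        assert mov.frames_a[:, 60, 50].max() == pytest.approx(2000.0, rel=1e-6)

    def test_center_outside_frame_rejected(self, ramp_pair):
        with pytest.raises(ValueError, match="center"):
            rp.synth.simulate_hotspot_movie(
                ramp_pair, rp.ChannelModel(g_max=4.0), center=(500.0, 50.0)
            )


class TestDeltaFImage:
    def test_peak_at_truth_center(self, noiseless_movie):
        img = imaging.delta_f_image(noiseless_movie)
        peak = np.unravel_index(np.argmax(img), img.shape)
        cy, cx = noiseless_movie.truth["center"]
        assert abs(peak[0] - cy) <= 1 and abs(peak[1] - cx) <= 1

    def test_too_few_baseline_frames_rejected(self, ramp_pair):
        with pytest.raises(ValueError, match="baseline"):
            rp.synth.simulate_hotspot_movie(
                ramp_pair, rp.ChannelModel(g_max=4.0), n_baseline=2
            )


class TestSelectHotspot:
    def test_strongest_plane_chosen(self, ramp_pair):
        # 7 planes with a bump of the drive at plane index 4
        scale = [0.1, 0.3, 0.6, 0.9, 1.6, 0.8, 0.2]
        imgs = []
        for i, s in enumerate(scale):
            mov = rp.synth.simulate_hotspot_movie(
                ramp_pair, rp.ChannelModel(g_max=4.0), dff_peak=s, noise_sd=1.0, seed=20 + i
            )
            imgs.append(imaging.delta_f_image(mov))
        plane, center = imaging.select_hotspot(imgs)
        assert plane == 4
        assert abs(center[0] - 60) <= 1 and abs(center[1] - 50) <= 1

    def test_single_plane(self):
        img = np.zeros((50, 50))
        img[10, 20] = 5.0
        assert imaging.select_hotspot([img]) == (0, (10, 20))

    def test_tie_breaks_to_earliest_plane(self):
        img = np.zeros((50, 50))
        img[10, 20] = 5.0
        plane, _ = imaging.select_hotspot([img.copy(), img.copy()])
        assert plane == 0

    def test_permutation_consistency(self, ramp_pair):
        imgs = []
        for i, s in enumerate([0.2, 1.5, 0.4]):
            mov = rp.synth.simulate_hotspot_movie(
                ramp_pair, rp.ChannelModel(g_max=4.0), dff_peak=s, noise_sd=1.0, seed=40 + i
            )
            imgs.append(imaging.delta_f_image(mov))
        p1, c1 = imaging.select_hotspot(imgs)
        p2, c2 = imaging.select_hotspot(imgs[::-1])
        assert imgs[p1][c1] == imgs[::-1][p2][c2]

    def test_all_zero_images_flagged(self):
        with pytest.raises(imaging.ImagingError, match="degenerate"):
            imaging.select_hotspot([np.zeros((50, 50))])


class TestExtractTrace:
    def test_dff_peak_matches_analytic(self, noiseless_movie):
        trace = imaging.extract_trace(noiseless_movie, (60, 50), which="a")
        analytic = noiseless_movie.truth["dff_3x3_a"].max()
        assert trace.dff.max() == pytest.approx(analytic, rel=0.10)

    def test_center_at_corner_rejected(self, noiseless_movie):
        with pytest.raises(imaging.ImagingError):
            imaging.extract_trace(noiseless_movie, (0, 0))

    def test_background_overlapping_spot_rejected(self, noiseless_movie):
        with pytest.raises(imaging.ImagingError, match="overlap"):
            imaging.extract_trace(noiseless_movie, (60, 50), bg_region=(30, 20))

    def test_zero_baseline_flagged(self, ramp_pair):
        # indicator with no resting fluorescence: baseline equals background
        ind = rp.IndicatorModel(k_d=10.0, f_min=1e-6, f_max=2000.0)
        mov = rp.synth.simulate_hotspot_movie(
            ramp_pair, rp.ChannelModel(g_max=4.0), ind, noise_sd=1.0, dff_peak=None, c_scale=0.01, seed=3
        )
        with pytest.raises(imaging.ImagingError, match="baseline"):
            imaging.extract_trace(mov, (60, 50))


class TestBuildFV:
    def test_merged_spacing_is_half_frame_spacing(self, noiseless_movie):
        ta = imaging.extract_trace(noiseless_movie, (60, 50), which="a")
        tb = imaging.extract_trace(noiseless_movie, (60, 50), which="b")
        fv = imaging.build_fv(ta, tb, (noiseless_movie.ramp_a, noiseless_movie.ramp_b))
        # 1 mV/ms ramp, 10 ms frames, 5 ms shift -> exactly 5 mV grid
        assert np.allclose(np.diff(fv.voltages), 5.0, atol=1e-9)
        assert fv.voltages[0] == pytest.approx(-87.0, abs=1e-6)

    def test_zero_shift_flags_duplicates(self):
        ramps = rp.synth.make_ramp_pair(shift=0.0)
        mov = rp.synth.simulate_hotspot_movie(ramps, rp.ChannelModel(g_max=4.0), noise_sd=0.0, seed=0)
        ta = imaging.extract_trace(mov, (60, 50), which="a")
        tb = imaging.extract_trace(mov, (60, 50), which="b")
        fv = imaging.build_fv(ta, tb, (mov.ramp_a, mov.ramp_b))
        assert fv.duplicate_voltages

    def test_mismatched_frame_counts_rejected(self, noiseless_movie):
        ta = imaging.extract_trace(noiseless_movie, (60, 50), which="a")
        tb = imaging.extract_trace(noiseless_movie, (60, 50), which="b")
        tb.time = tb.time[:-1]
        with pytest.raises(ValueError, match="frame count"):
            imaging.build_fv(ta, tb, (noiseless_movie.ramp_a, noiseless_movie.ramp_b))


class TestFitFV:
    def test_closed_form_recovery(self):
        # oracle: FV synthesized directly from the modified Boltzmann with the
        # WT single-AZ parameters; staged fit recovers both within 0.3 mV
        v = np.arange(-87.0, 64.0, 5.0)
        po = 1.0 / (1.0 + np.exp((-30.0 - v) / 5.79))
        fv = imaging.FVCurve(
            voltages=v, dff=0.03 * (45.0 - v) * po, source=np.repeat("a", len(v))
        )
        fit = imaging.fit_fv(fv)
        assert fit.v_half == pytest.approx(-30.0, abs=0.3)
        assert fit.k == pytest.approx(5.79, abs=0.3)

    def test_fractional_activation_matches_po_curve(self):
        v = np.arange(-87.0, 64.0, 5.0)
        po = 1.0 / (1.0 + np.exp((-30.0 - v) / 5.79))
        fv = imaging.FVCurve(voltages=v, dff=0.03 * (45.0 - v) * po, source=np.repeat("a", len(v)))
        fit = imaging.fit_fv(fv)
        po_at = 1.0 / (1.0 + np.exp((-30.0 - fit.frac_voltages) / 5.79))
        rms = np.sqrt(np.mean((fit.fractional_activation - po_at) ** 2))
        assert rms < 0.05
        assert np.all(np.diff(fit.fractional_activation) >= 0)

    def test_flat_fv_rejected(self):
        v = np.arange(-87.0, 64.0, 5.0)
        with pytest.raises(imaging.ImagingError, match="flat|activation"):
            imaging.fit_fv(imaging.FVCurve(voltages=v, dff=np.zeros_like(v), source=np.repeat("a", len(v))))

    def test_end_to_end_group_difference(self, ramp_pair):
        # simulated WT-like and KO-like AZ populations (counts as recorded):
        # the recovered mean v_half difference has the true sign and is
        # within 2 mV of the simulated truth difference
        rng = np.random.default_rng(77)
        means = {}
        truths = {}
        for tag, (vh, vh_sd, kk, k_sd, n) in {
            "wt": (-30.0, 6.5, 5.79, 2.04, 50),
            "ko": (-25.5, 7.49, 6.25, 1.7, 69),
        }.items():
            rec, tru = [], []
            for _ in range(n):
                m = rp.ChannelModel(
                    g_max=4.0, v_half=rng.normal(vh, vh_sd), k=max(2.0, rng.normal(kk, k_sd))
                )
                mov = rp.synth.simulate_hotspot_movie(ramp_pair, m, noise_sd=2.0, seed=rng)
                fit, _ = run_fv_pipeline(mov)
                rec.append(fit.v_half)
                tru.append(m.v_half)
            means[tag] = np.mean(rec)
            truths[tag] = np.mean(tru)
        rec_diff = means["ko"] - means["wt"]
        true_diff = truths["ko"] - truths["wt"]
        assert rec_diff > 0  # depolarized shift, as simulated
        assert abs(rec_diff - true_diff) < 2.0


class TestDffMax:
    def test_constant_stim_level(self, noiseless_movie):
        trace = imaging.extract_trace(noiseless_movie, (60, 50), which="a")
        trace.dff = np.where(trace.stim_mask, 1.6, 0.0)
        assert imaging.dff_max(trace) == pytest.approx(1.6)

    def test_all_zero_trace(self, noiseless_movie):
        trace = imaging.extract_trace(noiseless_movie, (60, 50), which="a")
        trace.dff = np.zeros_like(trace.dff)
        assert imaging.dff_max(trace) == 0.0

    def test_too_few_stim_frames_rejected(self, noiseless_movie):
        trace = imaging.extract_trace(noiseless_movie, (60, 50), which="a")
        trace.stim_mask = np.zeros_like(trace.stim_mask)
        with pytest.raises(imaging.ImagingError):
            imaging.dff_max(trace)

    def test_family_mean_tracks_analytic_maximum(self, ramp_pair):
        rng = np.random.default_rng(88)
        meas, truth = [], []
        for _ in range(12):
            mov = rp.synth.simulate_hotspot_movie(
                ramp_pair, rp.ChannelModel(g_max=4.0), noise_sd=2.0, seed=rng
            )
            trace = imaging.extract_trace(mov, (60, 50), which="a")
            meas.append(imaging.dff_max(trace))
            # oracle: analytic 5-consecutive-frame mean centered on the peak
            da = mov.truth["dff_3x3_a"]
            j = int(np.argmax(da))
            lo = min(max(0, j - 2), len(da) - 5)
            truth.append(da[lo : lo + 5].mean())
        meas = np.array(meas)
        sem = meas.std(ddof=1) / np.sqrt(len(meas))
        assert abs(meas.mean() - np.mean(truth)) < max(2 * sem, 0.05 * np.mean(truth))
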