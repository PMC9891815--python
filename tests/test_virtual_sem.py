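"""Forward model: specimen generation, rendering, noise scaling, streams."""

import math

import numpy as np
import pytest

from semfocus import (
    AcquisitionParams,
    OpticsState,
    estimate_snr,
    generate_specimen,
    ground_truth_snr,
    render_frame,
    stream,
)
from semfocus.frame_metrics import FramePair, sample_covariance
from semfocus.virtual_sem import (
    calibrate_dwell_scale,
    constant_trajectory,
    focus_ramp,
    noise_sd,
    psf_sigmas,
    render_pair,
)

ACQ = AcquisitionParams(width=128, height=128, seed=0)


class TestGenerateSpecimen:
    def test_same_seed_reproduces_texture_exactly(self):
        a = generate_specimen((256, 256), feature_scale=8.0, seed=42)
        b = generate_specimen((256, 256), feature_scale=8.0, seed=42)
        assert np.array_equal(a.texture, b.texture)

    def test_different_seeds_differ(self):
        a = generate_specimen((128, 128), seed=1)
        b = generate_specimen((128, 128), seed=2)
        assert not np.array_equal(a.texture, b.texture)

    def test_texture_normalised_to_requested_sd_and_mean(self):
        spec = generate_specimen((512, 512), texture_sd=2.0, mean_level=50.0, seed=3)
        assert spec.texture.mean() == pytest.approx(50.0, abs=0.2)
        assert spec.texture.std() == pytest.approx(2.0, rel=0.05)

    def test_block_size_makes_texture_block_constant(self):
        spec = generate_specimen((64, 64), feature_scale=4.0, block_size=4, seed=4)
        t = spec.texture.reshape(16, 4, 16, 4)
        assert np.allclose(t, t[:, :1, :, :1])

    def test_oversampled_texture_survives_block_averaging(self):
        # feature scale 16: a 2x2 average barely reduces the signal sd
        spec = generate_specimen((512, 512), feature_scale=16.0, seed=5)
        t = spec.texture
        red = t.reshape(256, 2, 256, 2).mean(axis=(1, 3))
        assert red.std() / t.std() > 0.95

    def test_strength_patch_scales_local_snr(self):
        # two regions with texture sd ratio 3 -> measured SNR ratio ~3
        patches = [{"offset": (-128.0, 0.0), "radius": 60, "strength": 3.0}]
        spec = generate_specimen((512, 512), feature_scale=4.0, patches=patches, seed=6)
        acq = AcquisitionParams(width=96, height=96, seed=7, dwell_scale=3.0)
        strong = estimate_snr(render_pair(spec, OpticsState(beam_shift=(-128.0, 0.0)), acq))
        plain = estimate_snr(render_pair(spec, OpticsState(beam_shift=(128.0, 0.0)), acq, tick=10))
        assert strong.snr / plain.snr == pytest.approx(3.0, rel=0.25)

    def test_invalid_feature_scale_rejected(self):
        with pytest.raises(ValueError):
            generate_specimen((64, 64), feature_scale=0.5)


class TestRenderFrame:
    def test_reproducible_from_seed_and_tick(self):
        spec = generate_specimen((512, 512), seed=8)
        f1 = render_frame(spec, OpticsState(), ACQ, tick=3)
        f2 = render_frame(spec, OpticsState(), ACQ, tick=3)
        assert np.array_equal(f1.pixels, f2.pixels)
        f3 = render_frame(spec, OpticsState(), ACQ, tick=4)
        assert not np.array_equal(f1.pixels, f3.pixels)

    def test_out_of_bounds_window_rejected(self):
        spec = generate_specimen((256, 256), seed=9)
        with pytest.raises(ValueError, match="outside specimen"):
            render_frame(spec, OpticsState(beam_shift=(300.0, 0.0)), ACQ)

    def test_focus_maximises_measured_snr(self):
        spec = generate_specimen((640, 640), feature_scale=4.0, seed=10)
        acq = calibrate_dwell_scale(spec, OpticsState(), ACQ, target_snr=1.0)
        snrs = {
            d: estimate_snr(render_pair(spec, OpticsState(defocus=d), acq)).snr
            for d in (-6.0, -3.0, 0.0, 3.0, 6.0)
        }
        assert max(snrs, key=snrs.get) == 0.0

    def test_quartered_current_halves_measured_snr(self):
        spec = generate_specimen((640, 640), feature_scale=6.0, seed=11)
        snr_hi, snr_lo = [], []
        for s in range(10):
            acq = AcquisitionParams(width=128, height=128, seed=100 + s, dwell_scale=2.0)
            snr_hi.append(estimate_snr(render_pair(spec, OpticsState(current=26.0), acq)).snr)
            snr_lo.append(estimate_snr(render_pair(spec, OpticsState(current=6.5), acq)).snr)
        assert np.mean(snr_hi) / np.mean(snr_lo) == pytest.approx(2.0, abs=0.2)

    def test_astigmatic_blur_is_anisotropic_at_line_focus(self):
        # defocus = astig magnitude: one principal direction at line focus
        spec = generate_specimen((640, 640), feature_scale=3.0, seed=12)
        optics = OpticsState(defocus=2.0, astig_x=2.0)
        su, sv, theta = psf_sigmas(optics, ACQ)
        assert sv == pytest.approx(0.0)
        assert theta == pytest.approx(0.0)
        from semfocus.virtual_sem import _render_clean

        clean = _render_clean(spec, optics, ACQ)
        gx = np.diff(clean, axis=1).var()  # gradients along blurred axis u=x
        gy = np.diff(clean, axis=0).var()
        assert gx < 0.5 * gy

    def test_isotropic_blur_at_zero_defocus_with_astigmatism(self):
        spec = generate_specimen((640, 640), feature_scale=3.0, seed=13)
        su, sv, _ = psf_sigmas(OpticsState(defocus=0.0, astig_y=1.5), ACQ)
        assert su == pytest.approx(sv)

    def test_magnification_oversamples_the_texture(self):
        spec = generate_specimen((640, 640), feature_scale=3.0, seed=14)
        from semfocus.virtual_sem import _render_clean

        zoomed = _render_clean(spec, OpticsState(magnification=4.0), ACQ)
        native = _render_clean(spec, OpticsState(), ACQ)
        # at 4x the same structures span 4x more pixels: 2x2 averaging
        # preserves the zoomed signal much better
        def retention(img):
            red = img.reshape(64, 2, 64, 2).mean(axis=(1, 3))
            return red.std() / img.std()

        assert retention(zoomed) > retention(native)

    def test_poisson_mode_matches_gaussian_amplitude_at_mean(self):
        from semfocus.virtual_sem import _render_clean

        spec = generate_specimen((512, 512), seed=15)
        acq_p = AcquisitionParams(width=128, height=128, seed=16, noise_model="poisson")
        optics = OpticsState()
        clean = _render_clean(spec, optics, acq_p)
        f = render_frame(spec, optics, acq_p)
        resid_sd = (f.pixels - clean).std()
        assert resid_sd == pytest.approx(noise_sd(optics, acq_p), rel=0.1)


class TestGroundTruth:
    def test_infinite_noise_limit_is_zero(self):
        spec = generate_specimen((512, 512), seed=17)
        acq = AcquisitionParams(width=128, height=128, dwell_scale=1e9)
        assert ground_truth_snr(spec, OpticsState(), acq) < 1e-6

    def test_doubling_texture_sd_doubles_ground_truth(self):
        a = generate_specimen((512, 512), texture_sd=1.0, seed=18)
        b = generate_specimen((512, 512), texture_sd=2.0, seed=18)
        sa = ground_truth_snr(a, OpticsState(), ACQ)
        sb = ground_truth_snr(b, OpticsState(), ACQ)
        assert sb / sa == pytest.approx(2.0, rel=1e-6)

    def test_estimator_consistent_with_ground_truth(self):
        spec = generate_specimen((640, 640), feature_scale=6.0, seed=19)
        optics = OpticsState(defocus=1.0)
        acq = calibrate_dwell_scale(spec, optics, ACQ, target_snr=0.5)
        truth = ground_truth_snr(spec, optics, acq)
        ests = [
            estimate_snr(render_pair(spec, optics, acq, tick=2 * s)).snr for s in range(10)
        ]
        assert np.mean(ests) == pytest.approx(truth, rel=0.1)

    def test_calibration_hits_target_snr(self):
        spec = generate_specimen((512, 512), feature_scale=5.0, seed=20)
        acq = calibrate_dwell_scale(spec, OpticsState(), ACQ, target_snr=0.1)
        assert ground_truth_snr(spec, OpticsState(), acq) == pytest.approx(0.1, rel=1e-9)


class TestStream:
    def test_constant_trajectory_gives_stationary_iid_noise(self):
        spec = generate_specimen((512, 512), seed=21)
        frames = stream(spec, constant_trajectory(OpticsState(), 4), ACQ)
        assert len(frames) == 4
        # noise-only residuals (true clean render subtracted) of two
        # frames are uncorrelated: cov sd ~ noise_var / sqrt(M)
        from semfocus.virtual_sem import _render_clean

        clean = _render_clean(spec, OpticsState(), ACQ)
        p = FramePair.from_arrays(frames[0].pixels - clean, frames[1].pixels - clean)
        nsd2 = noise_sd(OpticsState(), ACQ) ** 2
        assert abs(sample_covariance(p)) < 5 * nsd2 / math.sqrt(p.n_pixels)

    def test_byte_identical_reruns(self):
        spec = generate_specimen((512, 512), seed=22)
        traj = focus_ramp(-2, 2, 5)
        a = stream(spec, traj, ACQ)
        b = stream(spec, traj, ACQ)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.pixels, fb.pixels)

    def test_defocus_ramp_snr_series_is_unimodal(self):
        spec = generate_specimen((640, 640), feature_scale=4.0, seed=23)
        acq = calibrate_dwell_scale(spec, OpticsState(), ACQ, target_snr=2.0)
        traj = focus_ramp(-6, 6, 13)
        frames = stream(spec, traj, acq, frames_per_state=2)
        snrs = [
            estimate_snr(FramePair(frames[2 * i], frames[2 * i + 1])).snr for i in range(13)
        ]
        k = int(np.argmax(snrs))
        assert 4 <= k <= 8  # peak near the centre (defocus 0)

    def test_slow_scan_dwell_raises_snr_by_sqrt_ratio(self):
        spec = generate_specimen((640, 640), feature_scale=6.0, seed=24)
        acq = calibrate_dwell_scale(spec, OpticsState(), ACQ, target_snr=0.2)
        ratio = 100.0
        fast = [estimate_snr(render_pair(spec, OpticsState(), acq, tick=2 * s)).snr for s in range(8)]
        slow = [
            estimate_snr(render_pair(spec, OpticsState(), acq, tick=100 + 2 * s, dwell_multiplier=ratio)).snr
            for s in range(8)
        ]
        assert np.mean(slow) / np.mean(fast) == pytest.approx(math.sqrt(ratio), rel=0.1)

    def test_frame_metadata_carries_timing_and_controls(self):
        spec = generate_specimen((512, 512), seed=25)
        acq = AcquisitionParams(width=128, height=128, frame_rate=25.0, seed=26)
        frames = stream(spec, focus_ramp(-1, 1, 3), acq)
        meta = frames[0].meta
        assert meta["frame_time"] == 0.04
        assert meta["defocus"] == -1.0
        assert frames[-1].meta["defocus"] == 1.0
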