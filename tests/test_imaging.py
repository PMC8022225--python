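import numpy as np
import pandas as pd
import pytest

import targetsearch as ts
from targetsearch import imaging


def emitter_table(positions_px, n_frames, pixel_size=0.096):
    rows = [
        {"frame": f, "x_um": x * pixel_size, "y_um": y * pixel_size}
        for f in range(n_frames)
        for x, y in positions_px
    ]
    return pd.DataFrame(rows)


class TestRenderMovie:
    def test_zero_emitters_is_pure_background(self, acq):
        stack = imaging.render_movie(
            emitter_table([], 1), 0.12, 400, 10.0, acq, shape=(32, 32),
            n_frames=200, seed=0,
        )
        vals = stack.frames.ravel()
        assert vals.mean() == pytest.approx(10.0, rel=0.02)
        assert vals.var() == pytest.approx(10.0, rel=0.05)  # Poisson: var = mean

    def test_photon_conservation_without_noise(self, acq):
        stack = imaging.render_movie(
            emitter_table([(16.0, 16.0)], 1), 0.12, 500.0, 2.0, acq,
            shape=(32, 32), noise=False, seed=0,
        )
        excess = stack.frames[0].sum() - 2.0 * 32 * 32
        assert excess == pytest.approx(500.0, rel=1e-6)

    def test_per_pixel_variance_matches_mean(self, acq):
        stack = imaging.render_movie(
            emitter_table([(8.0, 8.0)], 1000), 0.15, 200.0, 5.0, acq,
            shape=(16, 16), seed=1,
        )
        mean = stack.frames.mean(axis=0)
        var = stack.frames.var(axis=0)
        slope = np.polyfit(mean.ravel(), var.ravel(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_out_of_raster_emitters_clipped(self, acq, caplog):
        locs = emitter_table([(100.0, 5.0)], 1)
        stack = imaging.render_movie(locs, 0.12, 400, 0.0, acq, shape=(32, 32),
                                     noise=False, seed=0)
        assert stack.frames.sum() == 0.0

    def test_tiff_roundtrip(self, acq, tmp_path):
        stack = imaging.render_movie(
            emitter_table([(10.0, 12.0)], 3), 0.12, 300, 4.0, acq,
            shape=(24, 24), seed=2,
        )
        path = tmp_path / "movie.tif"
        stack.save_tiff(path)
        back = imaging.FrameStack.load_tiff(path, stack.pixel_size)
        assert np.allclose(back.frames, stack.frames)


class TestDetection:
    def test_blank_movie_has_no_candidates(self, acq):
        stack = imaging.FrameStack(np.zeros((5, 32, 32)), acq.pixel_size)
        cands = imaging.detect_candidates(stack, threshold=1.0)
        assert all(len(c) == 0 for c in cands)

    def test_two_well_separated_emitters(self, acq):
        stack = imaging.render_movie(
            emitter_table([(8.0, 8.0), (28.0, 28.0)], 10), 0.12, 2000, 2.0, acq,
            shape=(40, 40), seed=3,
        )
        cands = imaging.detect_candidates(stack, threshold=20.0)
        assert all(len(c) == 2 for c in cands)

    def test_detection_rate_non_decreasing_in_snr(self, acq):
        rates = []
        for photons in (30, 150, 2000):
            stack = imaging.render_movie(
                emitter_table([(16.0, 16.0)], 40), 0.12, photons, 10.0, acq,
                shape=(32, 32), seed=4,
            )
            cands = imaging.detect_candidates(stack, threshold=8.0)
            rates.append(np.mean([len(c) > 0 for c in cands]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0

    def test_bad_bandpass_rejected(self, acq):
        stack = imaging.FrameStack(np.zeros((2, 16, 16)), acq.pixel_size)
        with pytest.raises(ValueError):
            imaging.detect_candidates(stack, bandpass_low=3.0, bandpass_high=1.0)


class TestLocalize:
    def test_subpixel_accuracy_at_high_snr(self, acq):
        stack = imaging.render_movie(
            emitter_table([(5.30, 7.80)], 30), 0.12, 10_000, 2.0, acq,
            shape=(16, 16), seed=5,
        )
        cands = imaging.detect_candidates(stack, threshold=30.0)
        locs, fits = imaging.localize(stack, cands, window=9)
        assert len(locs) == 30
        err_x = locs["x_um"] / acq.pixel_size - 5.30
        err_y = locs["y_um"] / acq.pixel_size - 7.80
        assert np.abs(err_x).max() < 0.1 and np.abs(err_y).max() < 0.1

    def test_isotropic_psf_flagged(self, acq):
        stack = imaging.render_movie(
            emitter_table([(8.0, 8.0)], 10), 0.12, 10_000, 1.0, acq,
            shape=(16, 16), seed=6,
        )
        cands = imaging.detect_candidates(stack, threshold=30.0)
        _, fits = imaging.localize(stack, cands)
        frac_iso = np.mean([f.isotropic for f in fits])
        widths = np.array([[f.width_x, f.width_y] for f in fits])
        assert np.allclose(widths[:, 0], widths[:, 1], rtol=0.15)
        assert frac_iso > 0.5

    def test_precision_scales_with_photon_count(self, acq):
        """RMS error ~ psf_sigma / sqrt(N) within a factor 1.5 (low background)."""
        psf_sigma, photons = 0.12, 1000
        stack = imaging.render_movie(
            emitter_table([(8.25, 8.6)], 150), psf_sigma, photons, 0.5, acq,
            shape=(16, 16), seed=7,
        )
        cands = imaging.detect_candidates(stack, threshold=10.0)
        locs, _ = imaging.localize(stack, cands)
        err = np.hypot(
            locs["x_um"] - 8.25 * acq.pixel_size, locs["y_um"] - 8.6 * acq.pixel_size
        )
        rms_1d = np.sqrt(np.mean(err**2) / 2)
        thompson = psf_sigma / np.sqrt(photons)
        assert thompson / 1.5 < rms_1d < thompson * 1.5

    def test_window_validation(self, acq):
        stack = imaging.FrameStack(np.zeros((1, 16, 16)), acq.pixel_size)
        with pytest.raises(ValueError):
            imaging.localize(stack, [np.array([[8, 8]])], window=4)


class TestRoundTrip:
    def test_detect_and_fit_recover_ground_truth(self, acq):
        """simulate -> render -> detect -> localize on well-separated emitters."""
        positions = [(8.0, 8.0), (8.0, 24.0), (24.0, 8.0), (24.0, 24.0)]
        n_frames = 15
        stack = imaging.render_movie(
            emitter_table(positions, n_frames), 0.12, 4000, 3.0, acq,
            shape=(32, 32), seed=8,
        )
        cands = imaging.detect_candidates(stack, threshold=25.0)
        locs, fits = imaging.localize(stack, cands)
        # detection count never exceeds the true emitter count...
        assert all(len(c) <= len(positions) for c in cands)
        # ...and >= 99% of emitter appearances are recovered close to truth
        truth = np.array(positions) * acq.pixel_size
        n_found = 0
        for _, row in locs.iterrows():
            d = np.hypot(truth[:, 0] - row["x_um"], truth[:, 1] - row["y_um"])
            if d.min() < 3 * 0.01:  # 3x the fitted precision scale (~10 nm)
                n_found += 1
        assert n_found / (len(positions) * n_frames) >= 0.99
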