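import numpy as np
import pytest
from scipy import integrate, stats

import targetsearch as ts
from targetsearch.dstar import DStarSample

from conftest import gamma_dstar


class TestTrackDstar:
    def test_stationary_track_gives_zero(self):
        frames = np.arange(5)
        assert ts.track_dstar(frames, np.ones(5), np.ones(5), 0.015) == 0.0

    def test_hand_arithmetic(self):
        """Four 0.1 µm steps at dt = 0.015 s: D* = 0.04/(4*4*0.015) = 1/6."""
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        d = ts.track_dstar(np.arange(5), x, np.zeros(5), 0.015)
        assert d == pytest.approx(1.0 / 6.0)

    def test_truncation_after_fifth_localization(self):
        frames = np.arange(10)
        x = np.concatenate([np.zeros(5), np.full(5, 100.0)])
        assert ts.track_dstar(frames, x, np.zeros(10), 0.015) == 0.0

    def test_rejects_short_and_gap_broken_tracks(self):
        assert ts.track_dstar(np.arange(4), np.zeros(4), np.zeros(4), 0.015) is None
        frames = np.array([0, 1, 3, 4, 5])  # gap within the first five points
        assert ts.track_dstar(frames, np.zeros(5), np.zeros(5), 0.015) is None

    def test_sample_from_tracks_counts_rejections(self):
        import pandas as pd

        rows = []
        for f in range(5):
            rows.append({"track_id": 0, "frame": f, "x_um": 0.1 * f, "y_um": 0.0, "cell_id": 0})
        for f in range(3):
            rows.append({"track_id": 1, "frame": f, "x_um": 0.0, "y_um": 0.0, "cell_id": 0})
        sample, n_rej = ts.sample_from_tracks(pd.DataFrame(rows), 0.015)
        assert len(sample) == 1 and n_rej == 1
        assert sample.values[0] == pytest.approx(1.0 / 6.0)


class TestDstarPdf:
    @pytest.mark.parametrize("d,n", [(0.5, 1), (1.0, 4), (3.3, 4), (0.04, 8)])
    def test_normalization(self, d, n):
        val, _ = integrate.quad(lambda x: ts.dstar_pdf(x, d, n), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_printed_formula_value(self):
        # n = 4, D = 1, x = 1: (1/6) 4^4 e^-4
        assert ts.dstar_pdf(1.0, 1.0, 4) == pytest.approx(256 * np.exp(-4) / 6, rel=1e-12)

    @pytest.mark.parametrize("d,n", [(0.7, 4), (2.0, 6)])
    def test_moments(self, d, n):
        mean, _ = integrate.quad(lambda x: x * ts.dstar_pdf(x, d, n), 0, np.inf)
        second, _ = integrate.quad(lambda x: x**2 * ts.dstar_pdf(x, d, n), 0, np.inf)
        assert mean == pytest.approx(d, rel=1e-8)
        assert second - mean**2 == pytest.approx(d**2 / n, rel=1e-6)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            ts.dstar_pdf(1.0, 0.0, 4)
        with pytest.raises(ValueError):
            ts.dstar_pdf(1.0, 1.0, 0)


class TestSingleFit:
    def test_mle_is_sample_mean(self):
        rng = np.random.default_rng(0)
        v = gamma_dstar(rng, 0.5, 10_000)
        fit = ts.fit_single(DStarSample(v, 0.01548))
        assert fit.d_star == pytest.approx(v.mean())
        assert abs(fit.d_star - 0.5) < 3 * 0.5 / (2 * 100)  # sd = D/sqrt(n*n_steps)

    def test_single_value(self):
        fit = ts.fit_single(DStarSample([0.42], 0.015))
        assert fit.d_star == pytest.approx(0.42)

    def test_estimator_is_unbiased(self):
        rng = np.random.default_rng(1)
        estimates = [
            ts.fit_single(DStarSample(gamma_dstar(rng, 1.0, 50), 0.015)).d_star
            for _ in range(1000)
        ]
        # sd of each estimate = 1/sqrt(200); mean of 1000 replicates ~ N(1, sd/sqrt(1000))
        assert np.mean(estimates) == pytest.approx(1.0, abs=3 * (1 / np.sqrt(200)) / np.sqrt(1000))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        v = gamma_dstar(rng, 0.8, 500)
        d1 = ts.fit_single(DStarSample(v, 0.015)).d_star
        d2 = ts.fit_single(DStarSample(10 * v, 0.015)).d_star
        assert d2 == pytest.approx(10 * d1)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            ts.fit_single(DStarSample(np.zeros(20), 0.015))


class TestMixtureFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        n = 20_000
        immobile = rng.uniform(size=n) < 0.3
        v = np.where(immobile, gamma_dstar(rng, 0.1, n), gamma_dstar(rng, 1.0, n))
        fit = ts.fit_mixture(DStarSample(v, 0.01548), seed=1)
        assert abs(fit.fraction_immobile - 0.3) <= 0.02
        assert abs(fit.d1_star - 0.1) / 0.1 <= 0.10
        assert abs(fit.d2_star - 1.0) / 1.0 <= 0.10

    def test_components_are_ordered(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([gamma_dstar(rng, 0.05, 500), gamma_dstar(rng, 2.0, 500)])
        fit = ts.fit_mixture(DStarSample(v, 0.01548), seed=2)
        assert fit.d1_star <= fit.d2_star

    def test_two_species_likelihood_dominates_single(self):
        rng = np.random.default_rng(7)
        for d in (0.3, 1.5):
            v = gamma_dstar(rng, d, 2000)
            s = DStarSample(v, 0.01548)
            assert ts.fit_mixture(s, seed=0).log_likelihood >= ts.fit_single(s).log_likelihood

    def test_no_spurious_immobile_population(self):
        """On a pure mobile sample the second species is not significant."""
        rng = np.random.default_rng(8)
        v = gamma_dstar(rng, 1.0, 5000)
        s = DStarSample(v, 0.01548, cell_ids=rng.integers(50, size=5000))
        fit = ts.fit_mixture(s, seed=3)
        single = ts.fit_single(s)
        lr = 2 * (fit.log_likelihood - single.log_likelihood)
        assert lr < 9  # no significant second species (chi2-scale)
        # any fitted immobile weight is either negligible or carried by a
        # component indistinguishable from the mobile one (collapse)
        assert fit.fraction_immobile < 0.1 or fit.d1_star > 0.5 * fit.d2_star


class TestBootstrap:
    def _sample(self, rng, n_cells=20, per_cell=30, d=0.8):
        values = gamma_dstar(rng, d, n_cells * per_cell)
        cells = np.repeat(np.arange(n_cells), per_cell)
        return DStarSample(values, 0.01548, cell_ids=cells)

    def test_identical_cells_give_zero_width(self):
        v = np.array([0.2, 0.5, 0.9])
        sample = DStarSample(
            np.tile(v, 4), 0.01548, cell_ids=np.repeat(np.arange(4), 3)
        )
        lo, hi = ts.bootstrap_cells(sample, "single", n_boot=100, seed=0)["d_star"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(9)
        sample = self._sample(rng)
        lo, hi = ts.bootstrap_cells(sample, "single", n_boot=300, seed=1)["d_star"]
        assert lo <= ts.fit_single(sample).d_star <= hi

    def test_single_cell_refused(self):
        sample = DStarSample([0.1, 0.2], 0.015, cell_ids=[0, 0])
        with pytest.raises(ValueError):
            ts.bootstrap_cells(sample, "single")

    def test_coverage_of_single_fit_ci(self):
        """~95% of bootstrap CIs should contain the true D."""
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            sample = self._sample(rng, n_cells=15, per_cell=20, d=1.0)
            lo, hi = ts.bootstrap_cells(
                sample, "single", n_boot=200, seed=int(rng.integers(2**31))
            )["d_star"]
            hits += lo <= 1.0 <= hi
        assert 0.85 <= hits / n_rep <= 1.0


class TestClassifyAndOffset:
    def test_boundary_convention(self):
        labels = ts.classify_tracks([0.0, 0.1499, 0.15, 1.0])
        assert labels.tolist() == ["immobile", "immobile", "mobile", "mobile"]

    def test_error_rate_matches_density_overlap(self):
        """Label error on a known 50/50 mixture equals the gamma-tail overlap."""
        rng = np.random.default_rng(11)
        n = 40_000
        slow = gamma_dstar(rng, 0.04, n // 2)
        fast = gamma_dstar(rng, 1.0, n // 2)
        labels = ts.classify_tracks(np.concatenate([slow, fast]))
        truth = np.array(["immobile"] * (n // 2) + ["mobile"] * (n // 2))
        err = np.mean(labels != truth)
        analytic = 0.5 * (
            stats.gamma.sf(0.15, a=4, scale=0.04 / 4)
            + stats.gamma.cdf(0.15, a=4, scale=1.0 / 4, )
        )
        assert err == pytest.approx(analytic, abs=0.01)

    def test_offset_correction_arithmetic(self):
        dt = 0.01548
        assert ts.offset_correct(0.035**2 / dt, 0.035, dt) == 0.0
        assert ts.offset_correct(0.11, 0.035, dt) == pytest.approx(0.11 - 0.035**2 / dt)
        # empirical fixed-cell baseline variant
        assert ts.offset_correct(0.11, baseline=0.07) == pytest.approx(0.04)
        assert ts.offset_correct(0.01, 0.035, dt) == 0.0  # floored
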