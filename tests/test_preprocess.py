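"""Preprocessing contracts: volume discarding, motion QC, nuisance
regression against a brute-force OLS oracle, filter pass/stop bands,
Gaussian smoothing against the closed-form kernel."""

import numpy as np
import pytest

from dcnet.containers import MotionTrace
from dcnet.preprocess import (PreprocessReport, PreprocessSettings, bandpass,
                              discard_initial_volumes, mean_mask_signal, motion_qc,
                              preprocess_subject, regress_nuisance, smooth_volume)
from .conftest import full_mask, make_series

SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def random_series(rng, shape=(4, 4, 4), t=60, tr=2.0):
    return make_series(rng.standard_normal(shape + (t,)), tr=tr)


class TestDiscard:
    def test_protocol_discard(self, rng):
        s = random_series(rng, t=212)
        out = discard_initial_volumes(s, 5)
        assert out.n_timepoints == 207
        assert np.array_equal(out.data, s.data[..., 5:])

    def test_zero_is_identity(self, rng):
        s = random_series(rng, t=10)
        assert discard_initial_volumes(s, 0) is s

    def test_discarding_everything_rejected(self, rng):
        s = random_series(rng, t=10)
        with pytest.raises(ValueError):
            discard_initial_volumes(s, 10)


class TestMotionQC:
    def test_zero_trace_retained(self):
        ex, row = motion_qc(MotionTrace(np.zeros((20, 6))))
        assert not ex and row["reason"] == ""

    def test_exceeding_translation_excluded(self):
        p = np.zeros((20, 6))
        p[7, 1] = 2.5
        ex, row = motion_qc(MotionTrace(p))
        assert ex and "translation" in row["reason"]

    def test_exact_threshold_retained(self):
        """The exclusion rule is strict: a 2.0 mm maximum stays in."""
        p = np.zeros((20, 6))
        p[3, 0] = 2.0
        p[5, 4] = 2.0
        ex, _ = motion_qc(MotionTrace(p))
        assert not ex

    def test_rotation_rule(self):
        p = np.zeros((20, 6))
        p[2, 5] = -2.4
        ex, row = motion_qc(MotionTrace(p))
        assert ex and "rotation" in row["reason"]

    def test_nonfinite_rejected(self):
        p = np.zeros((5, 6))
        p[1, 2] = np.nan
        with pytest.raises(ValueError):
            motion_qc(MotionTrace(p))


class TestNuisanceRegression:
    def test_intercept_only_demeans(self, rng):
        s = random_series(rng)
        out = regress_nuisance(s, None)
        assert np.allclose(out.data.mean(axis=-1), 0, atol=1e-10)

    def test_confound_column_fully_removed(self, rng):
        t = 50
        conf = rng.standard_normal((t, 1))
        data = np.tile(conf[:, 0], (3, 3, 3, 1))
        out = regress_nuisance(make_series(data), conf)
        assert np.abs(out.data).max() < 1e-8

    def test_matches_brute_force_ols(self, rng):
        """Residuals equal an explicit normal-equations solve."""
        t, k = 60, 8
        conf = rng.standard_normal((t, k))
        s = random_series(rng, shape=(3, 3, 2), t=t)
        out = regress_nuisance(s, conf)
        X = np.column_stack([np.ones(t), np.linspace(-1, 1, t), conf])
        beta = np.linalg.solve(X.T @ X, X.T @ s.data.reshape(-1, t).T)
        expected = s.data.reshape(-1, t).T - X @ beta
        assert np.allclose(out.data.reshape(-1, t).T, expected, atol=1e-10)

    def test_residuals_orthogonal_to_confounds(self, rng):
        t = 80
        conf = rng.standard_normal((t, 6))
        s = random_series(rng, t=t)
        out = regress_nuisance(s, conf)
        R = out.data.reshape(-1, t)
        for j in range(conf.shape[1]):
            c = conf[:, j]
            corr = np.abs(R @ c) / (np.linalg.norm(R, axis=1) * np.linalg.norm(c))
            assert corr.max() < 1e-6

    def test_rank_deficient_confounds_warn_not_fail(self, rng, caplog):
        t = 40
        c1 = rng.standard_normal(t)
        conf = np.column_stack([c1, 2 * c1])
        with caplog.at_level("WARNING"):
            out = regress_nuisance(random_series(rng, t=t), conf)
        assert "rank-deficient" in caplog.text
        assert np.all(np.isfinite(out.data))


class TestBandpass:
    def make_sine(self, freq_hz, t=207, tr=2.0):
        ts = np.arange(t) * tr
        sig = np.sin(2 * np.pi * freq_hz * ts)
        return make_series(np.tile(sig, (2, 2, 2, 1)), tr=tr), sig

    def test_passband_sine_preserved(self):
        s, sig = self.make_sine(0.05)
        out = bandpass(s)
        ratio = out.data[0, 0, 0].std() / sig.std()
        assert 0.95 <= ratio <= 1.05

    def test_stopband_sine_attenuated(self):
        s, sig = self.make_sine(0.2)
        out = bandpass(s)
        assert out.data[0, 0, 0].std() / sig.std() < 0.1

    def test_constant_series_zeroed(self):
        s = make_series(np.full((2, 2, 2, 64), 7.5))
        out = bandpass(s)
        assert np.abs(out.data).max() < 1e-10

    def test_band_above_nyquist_rejected(self):
        s = make_series(np.zeros((2, 2, 2, 64)), tr=2.0)
        with pytest.raises(ValueError):
            bandpass(s, 0.01, 0.3)  # Nyquist is 0.25 Hz at TR = 2 s


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        s = random_series(rng)
        assert smooth_volume(s, 0.0) is s

    def test_delta_matches_closed_form_gaussian(self):
        """6 mm FWHM on 3 mm voxels: per-axis sigma = 0.849 voxels; the
        smoothed delta equals the separable Gaussian kernel."""
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        out, _ = smooth_volume((vol, affine), 6.0)
        sigma = 6.0 * SIGMA / 3.0
        assert np.isclose(sigma, 0.8493, atol=1e-4)
        g1 = lambda d: np.exp(-d**2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        assert np.isclose(out[7, 7, 7], g1(0) ** 3, rtol=1e-3)
        assert np.isclose(out[8, 7, 7], g1(1) * g1(0) ** 2, rtol=1e-3)
        assert np.isclose(out[8, 8, 7], g1(1) ** 2 * g1(0), rtol=1e-3)

    def test_interior_mass_conserved(self):
        vol = np.zeros((21, 21, 21))
        vol[9:12, 9:12, 9:12] = 2.5
        out, _ = smooth_volume((vol, np.diag([3.0, 3, 3, 1])), 6.0)
        assert np.isclose(out.sum(), vol.sum(), rtol=1e-6)

    def test_constant_image_unchanged(self):
        vol = np.full((8, 8, 8), 3.3)
        out, _ = smooth_volume((vol, np.diag([3.0, 3, 3, 1])), 8.0)
        assert np.allclose(out, 3.3)

    def test_anisotropic_voxels_get_per_axis_sigma(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        affine = np.diag([2.0, 4.0, 3.0, 1.0])
        out, _ = smooth_volume((vol, affine), 6.0)
        # narrower voxels -> wider kernel in voxel units -> lower neighbors decay
        assert out[8, 7, 7] > out[7, 8, 7]

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_volume(random_series(rng), -1.0)


class TestPipeline:
    def test_deterministic_end_to_end(self, rng):
        s = random_series(rng, shape=(6, 6, 6), t=40)
        tr = MotionTrace(np.zeros((40, 6)))
        a = preprocess_subject(s, tr, settings=PreprocessSettings(n_discard=2))
        b = preprocess_subject(s, tr, settings=PreprocessSettings(n_discard=2))
        assert np.array_equal(a.data, b.data)

    def test_qc_recovers_planted_movers(self, rng):
        settings = PreprocessSettings(n_discard=0, smooth_fwhm_mm=0)
        report = PreprocessReport(settings=settings)
        excluded = []
        for i in range(6):
            p = np.zeros((30, 6))
            if i in (1, 4):
                p[5, 0] = 2.6
            s = random_series(rng, shape=(4, 4, 4), t=30)
            s.subject_id = f"s{i}"
            tr = MotionTrace(p, subject_id=f"s{i}")
            out = preprocess_subject(s, tr, settings=settings, report=report)
            if out is None:
                excluded.append(i)
        assert excluded == [1, 4]
        frame = report.to_frame()
        assert frame.excluded.sum() == 2

    def test_confound_signal_extraction(self, rng):
        s = random_series(rng, shape=(4, 4, 4), t=30)
        m = full_mask((4, 4, 4))
        sig = mean_mask_signal(s, m)
        assert np.allclose(sig, s.data.mean(axis=(0, 1, 2)))

    def test_mismatched_motion_length_rejected(self, rng):
        s = random_series(rng, t=40)
        tr = MotionTrace(np.zeros((30, 6)), aligned_to="discarded")
        with pytest.raises(ValueError, match="motion trace length"):
            preprocess_subject(s, tr, settings=PreprocessSettings(n_discard=5))
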