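"""Interpolation: PCI/LI baselines, natural cubic spline closed forms
against a dense-solver oracle, and separable 2-D grid upsampling."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline as SciCubicSpline

from splinesound.interpolation import (
    GridUpsampleConfig,
    SampledSeries,
    csi_upsample_grid,
    eval_spline,
    fit_cubic_spline,
    li_interpolate,
    pci_interpolate,
    stft_csi,
)
from splinesound.synthetic import make_case_a_series, make_case_b_signal
from splinesound.timefreq import STFTConfig, SpectrogramGrid, stft_spectrogram
from splinesound.audio import AudioRecord


def unit_series():
    return SampledSeries(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestPCIandLI:
    def test_pci_nearest_knot_rule(self):
        s = unit_series()
        assert pci_interpolate(s, 0.0) == 0.0
        assert pci_interpolate(s, 0.4) == 0.0
        assert pci_interpolate(s, 0.6) == 1.0

    def test_li_affine_rule(self):
        s = unit_series()
        assert li_interpolate(s, 0.5) == pytest.approx(0.5)
        assert li_interpolate(s, 1.0) == pytest.approx(1.0)

    def test_li_bounded_by_bracketing_knots(self, rng):
        t = np.arange(10.0)
        y = rng.standard_normal(10)
        s = SampledSeries(t, y)
        q = rng.uniform(0, 9, 50)
        vals = li_interpolate(s, q)
        lo = np.minimum(y[np.floor(q).astype(int)], y[np.ceil(q).astype(int)])
        hi = np.maximum(y[np.floor(q).astype(int)], y[np.ceil(q).astype(int)])
        assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)

    def test_out_of_range_query_rejected(self):
        with pytest.raises(ValueError):
            pci_interpolate(unit_series(), 1.5)
        with pytest.raises(ValueError):
            li_interpolate(unit_series(), -0.5)


class TestCubicSplineFit:
    def test_linear_knots_give_zero_curvature(self):
        t = np.arange(6.0)
        sp = fit_cubic_spline(SampledSeries(t, 2 * t))
        assert np.allclose(sp.M, 0.0, atol=1e-12)
        q = np.linspace(0, 5, 41)
        assert np.allclose(eval_spline(sp, q), 2 * q, atol=1e-12)

    def test_three_knot_tent_second_derivative(self):
        # interior equation: M0 + 4 M1 + M2 = 6(y0 - 2 y1 + y2)/q^2 = -12
        sp = fit_cubic_spline(SampledSeries(np.array([0.0, 1, 2]), np.array([0.0, 1, 0])))
        assert sp.M[1] == pytest.approx(-3.0)
        assert sp.M[0] == sp.M[2] == 0.0

    def test_interpolates_knots_exactly(self, rng):
        t = np.arange(9.0)
        y = rng.standard_normal(9)
        sp = fit_cubic_spline(SampledSeries(t, y))
        assert np.allclose(eval_spline(sp, t), y, atol=1e-12)
        assert np.allclose(sp.coeffs[:, 3], y[:-1])  # D_i = y_i

    def test_closed_forms_match_dense_solver_oracle(self, rng):
        """100 random uniform series: agree with an independent
        natural-spline solver to 1e-9 on dense query points."""
        for _ in range(100):
            n = int(rng.integers(4, 20))
            t0 = rng.uniform(-5, 5)
            q = rng.uniform(0.1, 3.0)
            t = t0 + q * np.arange(n)
            y = rng.standard_normal(n)
            ours = fit_cubic_spline(SampledSeries(t, y))
            oracle = SciCubicSpline(t, y, bc_type="natural")
            dense = np.linspace(t[0], t[-1], 7 * n)
            assert np.max(np.abs(eval_spline(ours, dense) - oracle(dense))) < 1e-9

    def test_c2_continuity_at_interior_knots(self):
        t, y = make_case_a_series(12)
        sp = fit_cubic_spline(SampledSeries(t, y))
        h = 1e-5
        for xk in t[1:-1]:
            for order, tol in ((1, 1e-6), (2, 1e-4)):
                if order == 1:
                    left = (eval_spline(sp, xk) - eval_spline(sp, xk - h)) / h
                    right = (eval_spline(sp, xk + h) - eval_spline(sp, xk)) / h
                else:
                    left = (
                        eval_spline(sp, xk) - 2 * eval_spline(sp, xk - h) + eval_spline(sp, xk - 2 * h)
                    ) / h**2
                    right = (
                        eval_spline(sp, xk + 2 * h) - 2 * eval_spline(sp, xk + h) + eval_spline(sp, xk)
                    ) / h**2
                scale = max(abs(left), abs(right), 1.0)
                assert abs(left - right) / scale < max(tol, 100 * h)

    def test_error_decreases_with_knot_doubling(self):
        dense = np.linspace(0, 11, 2000)
        errors = []
        for n in (12, 23, 45):
            t = np.linspace(0, 11, n)
            sp = fit_cubic_spline(SampledSeries(t, np.sin(2 * t)))
            errors.append(np.max(np.abs(eval_spline(sp, dense) - np.sin(2 * dense))))
        assert errors[1] < errors[0] and errors[2] < errors[1]

    def test_case_a_matches_oracle_at_half_point(self):
        t, y = make_case_a_series(12)
        ours = eval_spline(fit_cubic_spline(SampledSeries(t, y)), 0.5)
        oracle = SciCubicSpline(t, y, bc_type="natural")(0.5)
        assert ours == pytest.approx(float(oracle), abs=1e-9)

    def test_nonuniform_and_tiny_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_cubic_spline(SampledSeries(np.array([0.0, 1.0, 3.0]), np.zeros(3)))
        with pytest.raises(ValueError):
            fit_cubic_spline(SampledSeries(np.array([0.0, 1.0]), np.zeros(2)))


class TestGridUpsampling:
    def make_grid(self, values):
        values = np.asarray(values, dtype=float)
        return SpectrogramGrid(
            values=values,
            row_coords=np.arange(values.shape[0], dtype=float),
            col_coords=np.arange(values.shape[1], dtype=float),
            kind="stft",
        )

    def test_identity_factors(self, rng):
        g = self.make_grid(rng.random((5, 6)))
        out = csi_upsample_grid(g, GridUpsampleConfig(1, 1, "csi"))
        assert np.array_equal(out.values, g.values)

    def test_bilinear_ramp_reproduced_exactly(self):
        r, c = np.meshgrid(np.arange(5.0), np.arange(6.0), indexing="ij")
        g = self.make_grid(2.0 * r + 3.0 * c + 1.0)
        out = csi_upsample_grid(g, GridUpsampleConfig(2, 2, "csi"))
        rr, cc = np.meshgrid(np.arange(9) / 2.0, np.arange(11) / 2.0, indexing="ij")
        assert np.allclose(out.values, 2.0 * rr + 3.0 * cc + 1.0, atol=1e-12)

    def test_original_values_preserved(self, rng):
        g = self.make_grid(rng.random((5, 5)) + 1.0)
        out = csi_upsample_grid(g, GridUpsampleConfig(3, 2, "csi"))
        assert np.allclose(out.values[::3, ::2], g.values, atol=1e-12)

    def test_matches_separable_dense_oracle(self, rng):
        vals = rng.random((5, 5)) + 1.0  # positive, so clipping is inert
        g = self.make_grid(vals)
        out = csi_upsample_grid(g, GridUpsampleConfig(2, 2, "csi"))
        rows = np.arange(5.0)
        rq = np.arange(9) / 2.0
        pass1 = np.stack(
            [SciCubicSpline(rows, vals[:, j], bc_type="natural")(rq) for j in range(5)],
            axis=1,
        )
        cq = np.arange(9) / 2.0
        oracle = np.stack(
            [SciCubicSpline(rows, pass1[i], bc_type="natural")(cq) for i in range(9)],
            axis=0,
        )
        assert np.max(np.abs(out.values - oracle)) < 1e-9

    def test_all_methods_interpolate_knots(self, rng):
        g = self.make_grid(rng.random((4, 4)))
        for method in ("pci", "li", "csi"):
            out = csi_upsample_grid(g, GridUpsampleConfig(2, 2, method))
            assert np.allclose(out.values[::2, ::2], g.values, atol=1e-12)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            csi_upsample_grid(self.make_grid(np.ones((2, 5))))


class TestSTFTCSI:
    def record(self, freq=2000.0, fs=16000):
        t = np.arange(fs) / fs
        return AudioRecord(samples=np.sin(2 * np.pi * freq * t), sample_rate=fs)

    def test_row_count_for_default_fft(self):
        out = stft_csi(self.record(), STFTConfig(n_fft=256), GridUpsampleConfig(2, 1))
        assert out.shape[0] == 257

    def test_identity_factors_match_plain_stft(self):
        rec = self.record()
        a = stft_csi(rec, STFTConfig(), GridUpsampleConfig(1, 1))
        b = stft_spectrogram(rec, STFTConfig())
        assert np.array_equal(a.values, b.values)

    def test_tone_peak_within_one_original_bin(self):
        rec = self.record(freq=2040.0)
        out = stft_csi(rec, STFTConfig(), GridUpsampleConfig(2, 2))
        bin_hz = 16000 / 256
        peak_freqs = out.row_coords[np.argmax(out.values, axis=0)]
        assert np.all(np.abs(peak_freqs - 2040.0) <= bin_hz)


class TestMethodOrderingOnCaseB:
    def test_csi_beats_li_beats_pci_on_resolved_spectrum(self):
        """Reconstruction-error ordering CSI <= LI <= PCI in L2 on the
        two-component worked-example spectrum, with knots fine enough
        to resolve the (windowed) spectral mainlobes."""
        rec = make_case_b_signal(1000, 2.0)
        x = rec.samples * np.hanning(len(rec.samples))
        nfft = 8192
        mag = np.abs(np.fft.rfft(x, nfft)) * 4.0 / len(x)
        freqs = np.fft.rfftfreq(nfft, 1 / 1000)
        keep = freqs <= 30.0
        freqs, mag = freqs[keep], mag[keep]
        knots = np.arange(0, freqs.size, 4)
        series = SampledSeries(freqs[knots], mag[knots])
        dense = freqs[freqs <= freqs[knots][-1]]
        truth = mag[freqs <= freqs[knots][-1]]
        e_pci = np.linalg.norm(pci_interpolate(series, dense) - truth)
        e_li = np.linalg.norm(li_interpolate(series, dense) - truth)
        e_csi = np.linalg.norm(eval_spline(fit_cubic_spline(series), dense) - truth)
        assert e_csi <= e_li <= e_pci
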