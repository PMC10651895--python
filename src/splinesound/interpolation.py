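"""Piecewise-constant, linear and natural cubic-spline interpolation,
and separable 2-D spline upsampling of spectrogram grids (STFT-CSI).

The cubic spline is built from the closed forms for uniformly spaced
knots (x_i, y_i) with spacing q.  Writing M_i for the second derivative
at knot i, C2 continuity at the interior knots gives the tridiagonal
system

    M_{i-1} + 4 M_i + M_{i+1} = 6 (y_{i-1} - 2 y_i + y_{i+1}) / q^2

closed with natural ends M_0 = M_n = 0, and the per-interval cubic

    f_i(x) = A_i (x-x_i)^3 + B_i (x-x_i)^2 + C_i (x-x_i) + D_i

with A_i = (M_{i+1}-M_i)/(6q), B_i = M_i/2,
C_i = (y_{i+1}-y_i)/q - (M_{i+1}+2M_i) q/6 and D_i = y_i.

Spectrogram upsampling applies the 1-D spline along each axis in turn
(frequency first, then time); negative overshoot is clipped to zero so
the result remains a magnitude grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .audio import AudioRecord
from .timefreq import STFTConfig, SpectrogramGrid, stft_spectrogram

__all__ = [
    "SampledSeries",
    "CubicSplineFit",
    "GridUpsampleConfig",
    "pci_interpolate",
    "li_interpolate",
    "fit_cubic_spline",
    "eval_spline",
    "csi_upsample_grid",
    "stft_csi",
]


@dataclass(frozen=True)
class SampledSeries:
    """Discrete samples (t_n, gamma(t_n)) with strictly increasing t."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if t.ndim != 1 or t.shape != y.shape or t.size < 2:
            raise ValueError("t and y must be equal-length 1-D arrays of size >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class CubicSplineFit:
    """Natural cubic spline through uniform knots.

    ``coeffs`` has one row (A_i, B_i, C_i, D_i) per interval; ``M`` are
    the knot second derivatives with M[0] = M[-1] = 0.
    """

    knots_x: np.ndarray
    knots_y: np.ndarray
    q: float
    M: np.ndarray
    coeffs: np.ndarray  # (n_intervals, 4)


@dataclass(frozen=True)
class GridUpsampleConfig:
    freq_factor: int = 2
    time_factor: int = 2
    method: str = "csi"

    def __post_init__(self) -> None:
        if self.freq_factor < 1 or self.time_factor < 1:
            raise ValueError("upsample factors must be >= 1")
        if self.method not in ("pci", "li", "csi"):
            raise ValueError("method must be one of pci, li, csi")


def _check_range(t: np.ndarray, t_query: np.ndarray) -> np.ndarray:
    tq = np.atleast_1d(np.asarray(t_query, dtype=np.float64))
    if np.any(tq < t[0] - 1e-12) or np.any(tq > t[-1] + 1e-12):
        raise ValueError("query outside the knot range (no extrapolation)")
    return np.clip(tq, t[0], t[-1])


def pci_interpolate(series: SampledSeries, t_query) -> np.ndarray | float:
    """Piecewise-constant (nearest-knot) interpolation, gamma*(t) = gamma(t_n)."""
    tq = _check_range(series.t, t_query)
    mid = 0.5 * (series.t[:-1] + series.t[1:])
    idx = np.searchsorted(mid, tq, side="left")
    out = series.y[idx]
    return out if np.ndim(t_query) else float(out[0])


def li_interpolate(series: SampledSeries, t_query) -> np.ndarray | float:
    """Linear interpolation between the two bracketing knots."""
    tq = _check_range(series.t, t_query)
    out = np.interp(tq, series.t, series.y)
    return out if np.ndim(t_query) else float(out[0])


def _uniform_spacing(t: np.ndarray) -> float:
    dt = np.diff(t)
    q = float(dt.mean())
    if np.max(np.abs(dt - q)) > 1e-9 * max(abs(q), 1.0):
        raise ValueError("knots must be uniformly spaced")
    return q


def _natural_second_derivatives(y: np.ndarray, q: float) -> np.ndarray:
    """Solve the tridiagonal continuity system with natural ends."""
    n = y.size
    M = np.zeros_like(y)
    if n > 2:
        rhs = 6.0 * (y[:-2] - 2.0 * y[1:-1] + y[2:]) / q**2
        ab = np.empty((3, n - 2))
        ab[0, :] = 1.0  # super-diagonal
        ab[1, :] = 4.0  # diagonal
        ab[2, :] = 1.0  # sub-diagonal
        M[1:-1] = solve_banded((1, 1), ab, rhs)
    return M


def fit_cubic_spline(series: SampledSeries) -> CubicSplineFit:
    """Fit a natural cubic spline through >= 3 uniformly spaced knots."""
    if series.t.size < 3:
        raise ValueError("need at least 3 knots")
    q = _uniform_spacing(series.t)
    y = series.y
    M = _natural_second_derivatives(y, q)
    A = (M[1:] - M[:-1]) / (6.0 * q)
    B = M[:-1] / 2.0
    C = (y[1:] - y[:-1]) / q - (M[1:] + 2.0 * M[:-1]) * q / 6.0
    D = y[:-1].copy()
    coeffs = np.stack([A, B, C, D], axis=1)
    return CubicSplineFit(knots_x=series.t, knots_y=y, q=q, M=M, coeffs=coeffs)


def eval_spline(spline: CubicSplineFit, t_query) -> np.ndarray | float:
    """Evaluate the piecewise cubic; queries must lie inside the knot range."""
    tq = _check_range(spline.knots_x, t_query)
    idx = np.clip(
        np.searchsorted(spline.knots_x, tq, side="right") - 1,
        0,
        spline.coeffs.shape[0] - 1,
    )
    dx = tq - spline.knots_x[idx]
    A, B, C, D = (spline.coeffs[idx, k] for k in range(4))
    out = ((A * dx + B) * dx + C) * dx + D
    return out if np.ndim(t_query) else float(out[0])


def _upsample_axis0(values: np.ndarray, factor: int, method: str) -> np.ndarray:
    """Refine axis 0 of a 2-D array from n to (n-1)*factor + 1 samples."""
    n = values.shape[0]
    if factor == 1 or n < 2:
        return values.copy()
    x = np.arange(n, dtype=np.float64)
    xq = np.arange((n - 1) * factor + 1, dtype=np.float64) / factor
    if method == "csi":
        M = _natural_second_derivatives_multi(values)
        idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, n - 2)
        dx = (xq - x[idx])[:, None]
        y0, y1 = values[idx], values[idx + 1]
        M0, M1 = M[idx], M[idx + 1]
        A = (M1 - M0) / 6.0
        B = M0 / 2.0
        C = (y1 - y0) - (M1 + 2.0 * M0) / 6.0
        return ((A * dx + B) * dx + C) * dx + y0
    if method == "li":
        idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, n - 2)
        w = (xq - x[idx])[:, None]
        return values[idx] * (1 - w) + values[idx + 1] * w
    # pci: nearest knot
    idx = np.round(xq).astype(int)
    return values[idx].copy()


def _natural_second_derivatives_multi(values: np.ndarray) -> np.ndarray:
    """Natural-spline second derivatives for every column at once (q = 1)."""
    n = values.shape[0]
    M = np.zeros_like(values)
    if n > 2:
        rhs = 6.0 * (values[:-2] - 2.0 * values[1:-1] + values[2:])
        ab = np.empty((3, n - 2))
        ab[0, :] = 1.0
        ab[1, :] = 4.0
        ab[2, :] = 1.0
        M[1:-1] = solve_banded((1, 1), ab, rhs)
    return M


def _refined_coords(coords: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1 or coords.size < 2:
        return coords.copy()
    n = coords.size
    xq = np.arange((n - 1) * factor + 1, dtype=np.float64) / factor
    return np.interp(xq, np.arange(n, dtype=np.float64), coords)


def csi_upsample_grid(
    grid: SpectrogramGrid, cfg: GridUpsampleConfig = GridUpsampleConfig()
) -> SpectrogramGrid:
    """Upsample a spectrogram by separable per-axis interpolation.

    Frequency axis first, then time.  Output has (rows-1)*freq_factor+1
    rows and (cols-1)*time_factor+1 columns; the original grid values
    are preserved at their positions.  For the spline method negative
    overshoot is clipped to zero to keep the grid a magnitude.
    """
    if grid.values.shape[0] < 3 or grid.values.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    vals = _upsample_axis0(grid.values, cfg.freq_factor, cfg.method)
    vals = _upsample_axis0(vals.T, cfg.time_factor, cfg.method).T
    if cfg.method == "csi":
        vals = np.maximum(vals, 0.0)
    return SpectrogramGrid(
        values=vals,
        row_coords=_refined_coords(grid.row_coords, cfg.freq_factor),
        col_coords=_refined_coords(grid.col_coords, cfg.time_factor),
        kind=grid.kind,
    )


def stft_csi(
    record: AudioRecord,
    stft_cfg: STFTConfig = STFTConfig(),
    up_cfg: GridUpsampleConfig = GridUpsampleConfig(),
) -> SpectrogramGrid:
    """STFT magnitude spectrogram followed by cubic-spline upsampling."""
    return csi_upsample_grid(stft_spectrogram(record, stft_cfg), up_cfg)
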