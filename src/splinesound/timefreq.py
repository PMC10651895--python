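"""Time-frequency representations: FFT spectrum, STFT, Mel, Haar CWT.

Three complementary views of the same record feed the classifier:

* an STFT magnitude spectrogram (Hanning window, 256-point FFT, 75%
  overlap by default) — fine temporal structure;
* a mel-band energy spectrogram (1024-sample window, 64 bands) built on
  the perceptual scale mel(f) = 2595 log10(1 + f/700);
* a Haar continuous-wavelet scalogram (squared coefficient magnitude
  over scale x time) — multi-resolution view favouring low frequencies.

A plain one-sided FFT spectrum is also provided for the worked
examples, with an optional 2/N amplitude scaling under which an
integer-period sinusoid of amplitude a peaks at exactly a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve, get_window

from .audio import AudioRecord

__all__ = [
    "STFTConfig",
    "MelConfig",
    "CWTConfig",
    "SpectrogramGrid",
    "SpectrumSeries",
    "fft_spectrum",
    "stft_spectrogram",
    "mel_spectrogram",
    "haar_cwt_scalogram",
    "haar_wavelet",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
]


@dataclass(frozen=True)
class STFTConfig:
    window_kind: str = "hann"
    n_fft: int = 256
    overlap_frac: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.n_fft < 16 or (self.n_fft & (self.n_fft - 1)) != 0:
            raise ValueError("n_fft must be a power of two >= 16")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.n_fft * (1.0 - self.overlap_frac))))


@dataclass(frozen=True)
class MelConfig:
    n_fft: int = 1024
    n_mels: int = 64
    f_min: float = 0.0
    f_max: float | None = None  # defaults to Nyquist at transform time
    overlap_frac: float = 0.75

    def __post_init__(self) -> None:
        if self.n_mels < 2:
            raise ValueError("n_mels must be >= 2")
        if self.f_max is not None and self.f_min >= self.f_max:
            raise ValueError("need f_min < f_max")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.n_fft * (1.0 - self.overlap_frac))))


@dataclass(frozen=True)
class CWTConfig:
    wavelet: str = "haar"
    window_len: int = 512
    n_scales: int = 128
    scale_min: int = 2
    scale_max: int | None = None  # defaults to window_len

    def __post_init__(self) -> None:
        if self.wavelet != "haar":
            raise ValueError("only the Haar wavelet is supported")
        if self.scale_min < 2:
            raise ValueError("scale_min must be >= 2")
        smax = self.window_len if self.scale_max is None else self.scale_max
        if smax > self.window_len:
            raise ValueError("scale_max must not exceed window_len")
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")

    @property
    def effective_scale_max(self) -> int:
        return self.window_len if self.scale_max is None else self.scale_max

    @property
    def hop(self) -> int:
        return max(1, self.window_len // 4)

    def scales(self) -> np.ndarray:
        """Log-spaced even integer scales (even so the discretized Haar
        kernel has exactly zero mean), duplicates removed."""
        raw = np.geomspace(self.scale_min, self.effective_scale_max, self.n_scales)
        even = np.clip(2 * np.round(raw / 2.0).astype(int), 2, self.effective_scale_max)
        return np.unique(even)


@dataclass(frozen=True)
class SpectrogramGrid:
    """2-D non-negative magnitude array over (freq-or-scale, time)."""

    values: np.ndarray
    row_coords: np.ndarray  # Hz or scale (samples)
    col_coords: np.ndarray  # seconds
    kind: str  # {stft, mel, scalogram}

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        rows = np.asarray(self.row_coords, dtype=np.float64)
        cols = np.asarray(self.col_coords, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.any(values < 0):
            raise ValueError("magnitude values must be non-negative")
        if rows.shape != (values.shape[0],) or cols.shape != (values.shape[1],):
            raise ValueError("coordinate vectors must match array dimensions")
        if rows.size > 1 and not np.all(np.diff(rows) > 0):
            raise ValueError("row_coords must be strictly increasing")
        if cols.size > 1 and not np.all(np.diff(cols) > 0):
            raise ValueError("col_coords must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_coords", rows)
        object.__setattr__(self, "col_coords", cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SpectrumSeries:
    freqs: np.ndarray
    magnitudes: np.ndarray
    scaling: str

    def peak_frequencies(self, n_peaks: int = 2, exclude_dc: bool = True) -> np.ndarray:
        """Frequencies of the n largest local spectral maxima."""
        mags = self.magnitudes.copy()
        if exclude_dc:
            mags[0] = 0.0
        order = np.argsort(mags)[::-1]
        picked: list[int] = []
        for idx in order:
            if all(abs(idx - p) > 1 for p in picked):
                picked.append(int(idx))
            if len(picked) == n_peaks:
                break
        return self.freqs[picked]


def fft_spectrum(record: AudioRecord, scaling: str = "amplitude") -> SpectrumSeries:
    """One-sided FFT magnitude spectrum of a record.

    With ``scaling="amplitude"`` the magnitudes are multiplied by 2/N
    (DC and Nyquist bins by 1/N) so a pure sinusoid of amplitude a with
    an integer number of periods in the window peaks at exactly a.
    """
    if len(record) == 0:
        raise ValueError("empty record")
    n = len(record)
    spec = np.abs(np.fft.rfft(record.samples))
    if scaling == "amplitude":
        spec = spec * (2.0 / n)
        spec[0] /= 2.0
        if n % 2 == 0:
            spec[-1] /= 2.0
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    freqs = np.fft.rfftfreq(n, 1.0 / record.sample_rate)
    return SpectrumSeries(freqs=freqs, magnitudes=spec, scaling=scaling)


def _frames(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """(n_frames, frame_len) view: frame k starts at sample k*hop."""
    if x.size < frame_len:
        raise ValueError("record shorter than one analysis window")
    return sliding_window_view(x, frame_len)[::hop]


def stft_spectrogram(record: AudioRecord, cfg: STFTConfig = STFTConfig()) -> SpectrogramGrid:
    """Short-time Fourier magnitude spectrogram.

    Frame count is 1 + floor((N - n_fft)/hop) with hop =
    n_fft*(1 - overlap_frac); rows are the n_fft/2 + 1 one-sided bins.
    """
    win = get_window(cfg.window_kind, cfg.n_fft, fftbins=True)
    frames = _frames(record.samples, cfg.n_fft, cfg.hop)
    mags = np.abs(np.fft.rfft(frames * win, axis=1)).T
    freqs = np.fft.rfftfreq(cfg.n_fft, 1.0 / record.sample_rate)
    starts = np.arange(frames.shape[0]) * cfg.hop
    times = (starts + cfg.n_fft / 2.0) / record.sample_rate
    return SpectrogramGrid(values=mags, row_coords=freqs, col_coords=times, kind="stft")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """Perceptual mel scale, mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int, n_fft: int, n_mels: int, f_min: float, f_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular, area-normalized mel filters over the one-sided bins.

    Returns (weights with shape (n_mels, n_fft//2+1), band centre
    frequencies in Hz).
    """
    if f_max > sample_rate / 2.0 + 1e-9:
        raise ValueError("f_max exceeds Nyquist")
    fft_freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    mel_pts = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    weights = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        weights[m] = tri * (2.0 / (hi - lo))  # area normalization
    return weights, hz_pts[1:-1]


def mel_spectrogram(record: AudioRecord, cfg: MelConfig = MelConfig()) -> SpectrogramGrid:
    """Mel-band energy spectrogram (power spectrum through the filterbank)."""
    f_max = cfg.f_max if cfg.f_max is not None else record.sample_rate / 2.0
    if f_max > record.sample_rate / 2.0 + 1e-9:
        raise ValueError("f_max exceeds Nyquist")
    win = get_window("hann", cfg.n_fft, fftbins=True)
    frames = _frames(record.samples, cfg.n_fft, cfg.hop)
    power = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    weights, centers = mel_filterbank(
        record.sample_rate, cfg.n_fft, cfg.n_mels, cfg.f_min, f_max
    )
    mels = (weights @ power.T)
    starts = np.arange(frames.shape[0]) * cfg.hop
    times = (starts + cfg.n_fft / 2.0) / record.sample_rate
    return SpectrogramGrid(values=mels, row_coords=centers, col_coords=times, kind="mel")


def haar_wavelet(t: np.ndarray | float) -> np.ndarray | float:
    """Haar mother wavelet: 1 on [0, 1/2), -1 on [1/2, 1), 0 elsewhere."""
    t = np.asarray(t, dtype=np.float64)
    out = np.where((t >= 0.0) & (t < 0.5), 1.0, np.where((t >= 0.5) & (t < 1.0), -1.0, 0.0))
    return out if out.ndim else float(out)


def haar_cwt_scalogram(record: AudioRecord, cfg: CWTConfig = CWTConfig()) -> SpectrogramGrid:
    """Haar continuous-wavelet scalogram (squared coefficient magnitude).

    The CWT integral is discretized as a finite sum with unit sample
    spacing: coefficient(scale, tau) = sum_n x[n] Psi((n - tau)/scale)
    / sqrt(scale).  Rows are logarithmically spaced integer scales,
    columns are positions every window_len/4 samples.
    """
    x = record.samples
    smax = cfg.effective_scale_max
    if x.size < smax:
        raise ValueError("record shorter than the largest scale")
    scales = cfg.scales()
    hop = cfg.hop
    positions = np.arange(0, x.size - smax + 1, hop)
    if positions.size == 0:
        positions = np.array([0])
    grid = np.empty((scales.size, positions.size))
    for i, lam in enumerate(scales):
        half = lam // 2
        kernel = np.empty(lam)
        kernel[:half] = 1.0
        kernel[half:] = -1.0
        kernel /= np.sqrt(lam)
        # full correlation with the causal wavelet support [tau, tau+lam)
        coeffs = fftconvolve(x, kernel[::-1], mode="valid")
        grid[i] = coeffs[positions] ** 2
    times = (positions + smax / 2.0) / record.sample_rate
    return SpectrogramGrid(
        values=grid, row_coords=scales.astype(float), col_coords=times, kind="scalogram"
    )
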