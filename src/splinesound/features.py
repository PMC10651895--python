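"""RGB feature spectrograms.

The three time-frequency grids of one record are converted to decibel
images, min-max normalized per image, resized to a common square size
and stacked into a three-channel image with the fixed channel
assignment (R, G, B) = (mel spectrogram, spline-interpolated STFT,
Haar scalogram).  That stacked image is the classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .audio import AudioRecord
from .interpolation import GridUpsampleConfig, stft_csi
from .timefreq import (
    CWTConfig,
    MelConfig,
    STFTConfig,
    SpectrogramGrid,
    haar_cwt_scalogram,
    mel_spectrogram,
)

__all__ = [
    "ImageChannel",
    "RGBSpectrogram",
    "FeaturizeConfig",
    "grid_to_channel",
    "stack_rgb",
    "featurize_record",
    "save_png",
    "load_png",
]


@dataclass(frozen=True)
class ImageChannel:
    """A square image channel with pixel values in [0, 1].

    Row 0 is the top of the image; low frequencies (or large scales)
    sit at the bottom row.
    """

    pixels: np.ndarray
    source_kind: str  # {mel, stft_csi, scalogram}

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("channel must be a square 2-D array")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValueError("pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))


@dataclass(frozen=True)
class RGBSpectrogram:
    """Stacked (R, G, B) = (mel, stft_csi, scalogram) feature image."""

    channels: tuple[ImageChannel, ImageChannel, ImageChannel]
    label: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        shapes = {ch.pixels.shape for ch in self.channels}
        if len(shapes) != 1:
            raise ValueError("all three channels must share one shape")

    @property
    def array(self) -> np.ndarray:
        """H x W x 3 float array in [0, 1]."""
        return np.stack([ch.pixels for ch in self.channels], axis=-1)

    @property
    def image_size(self) -> int:
        return self.channels[0].pixels.shape[0]


@dataclass(frozen=True)
class FeaturizeConfig:
    """Bundle of per-transform configs plus image conversion settings.

    ``image_size`` defaults to 128 (the encoder's 128x128x3 input); 224
    matches the plain-CNN configuration and is available by override.
    """

    stft: STFTConfig = field(default_factory=STFTConfig)
    mel: MelConfig = field(default_factory=MelConfig)
    cwt: CWTConfig = field(default_factory=CWTConfig)
    upsample: GridUpsampleConfig = field(default_factory=GridUpsampleConfig)
    image_size: int = 128
    db_floor: float = -80.0


def grid_to_channel(
    grid: SpectrogramGrid, image_size: int = 128, db_floor: float = -80.0
) -> ImageChannel:
    """Convert a magnitude grid to a normalized square image channel.

    The grid is mapped to decibels relative to its own maximum
    (20 log10), floored at ``db_floor``, min-max normalized to [0, 1]
    and bilinearly resized.  A constant grid maps to all zeros.  The
    per-image normalization deliberately removes recording gain, so
    doubling all magnitudes leaves the channel unchanged.
    """
    if grid.values.size == 0:
        raise ValueError("empty grid")
    vals = grid.values
    ref = vals.max()
    if ref <= 0:
        db = np.full_like(vals, db_floor)
    else:
        db = 20.0 * np.log10(np.maximum(vals, 1e-300) / ref)
        db = np.maximum(db, db_floor)
    lo, hi = db.min(), db.max()
    norm = np.zeros_like(db) if hi - lo < 1e-12 else (db - lo) / (hi - lo)
    # row 0 of the grid is the lowest frequency; flip so it is the bottom row
    img = Image.fromarray(np.flipud(norm).astype(np.float32), mode="F")
    img = img.resize((image_size, image_size), Image.Resampling.BILINEAR)
    return ImageChannel(pixels=np.asarray(img, dtype=np.float64), source_kind=grid.kind)


def stack_rgb(
    mel_ch: ImageChannel, stftcsi_ch: ImageChannel, scal_ch: ImageChannel
) -> RGBSpectrogram:
    """Stack the three channels in the fixed (R, G, B) order, unmodified."""
    if not (mel_ch.pixels.shape == stftcsi_ch.pixels.shape == scal_ch.pixels.shape):
        raise ValueError("channel shapes differ")
    return RGBSpectrogram(channels=(mel_ch, stftcsi_ch, scal_ch))


def featurize_record(
    record: AudioRecord, cfg: FeaturizeConfig = FeaturizeConfig()
) -> RGBSpectrogram:
    """Full feature extraction for one record: three transforms, stacked."""
    mel_ch = grid_to_channel(mel_spectrogram(record, cfg.mel), cfg.image_size, cfg.db_floor)
    stft_ch = grid_to_channel(
        stft_csi(record, cfg.stft, cfg.upsample), cfg.image_size, cfg.db_floor
    )
    stft_ch = ImageChannel(pixels=stft_ch.pixels, source_kind="stft_csi")
    scal_ch = grid_to_channel(haar_cwt_scalogram(record, cfg.cwt), cfg.image_size, cfg.db_floor)
    rgb = stack_rgb(mel_ch, stft_ch, scal_ch)
    return RGBSpectrogram(channels=rgb.channels, label=record.label)


def save_png(rgb: RGBSpectrogram, path: str | Path) -> None:
    """Write the stacked image as 8-bit RGB PNG."""
    arr = np.round(rgb.array * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def load_png(path: str | Path, label: str | None = None) -> RGBSpectrogram:
    arr = np.asarray(Image.open(Path(path)).convert("RGB"), dtype=np.float64) / 255.0
    channels = tuple(
        ImageChannel(pixels=arr[:, :, k], source_kind=kind)
        for k, kind in enumerate(("mel", "stft_csi", "scalogram"))
    )
    return RGBSpectrogram(channels=channels, label=label, source_path=str(path))
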