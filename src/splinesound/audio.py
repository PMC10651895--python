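"""WAV audio input/output and fixed-length segmentation.

Recordings are held as :class:`AudioRecord`, a mono float waveform in
[-1, 1] with its sample rate and an optional class label.  Long
recordings are cut into contiguous, non-overlapping fixed-length records
(5 s for biotic calls, much longer for propeller-like sources) before
any time-frequency processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioRecord",
    "SegmentationConfig",
    "read_wav",
    "write_wav",
    "segment",
]

_PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class AudioRecord:
    """A mono sampled waveform with sample rate and optional label."""

    samples: np.ndarray
    sample_rate: int
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioRecord holds mono audio (1-D samples)")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SegmentationConfig:
    """How to cut a recording into fixed-length records.

    ``segment_s`` may be overridden per class through ``per_class``
    (label -> seconds), mirroring pipelines where biotic calls use short
    records and propeller-like sources much longer ones.
    """

    segment_s: float = 5.0
    drop_last_partial: bool = True
    resample_to: int | None = None
    per_class: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")
        for label, secs in self.per_class.items():
            if secs <= 0:
                raise ValueError(f"segment_s for class {label!r} must be positive")

    def seconds_for(self, label: str | None) -> float:
        if label is not None and label in self.per_class:
            return self.per_class[label]
        return self.segment_s


def read_wav(path: str | Path, label: str | None = None) -> AudioRecord:
    """Read a RIFF/WAV file as a mono record scaled to [-1, 1].

    Multi-channel audio is averaged down to mono.  Integer PCM sample
    formats are scaled by their full-scale value; float WAVs are taken
    as already normalized.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"not a readable WAV file: {path}") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioRecord(samples=data, sample_rate=int(rate), label=label)


def write_wav(path: str | Path, record: AudioRecord) -> None:
    """Write a record as PCM-16 WAV, clipping to the representable range."""
    pcm = np.clip(record.samples, -1.0, 1.0 - 1.0 / _PCM16_SCALE)
    pcm = np.round(pcm * _PCM16_SCALE).astype(np.int16)
    wavfile.write(Path(path), record.sample_rate, pcm)


def _resampled(record: AudioRecord, target_rate: int) -> AudioRecord:
    if record.sample_rate == target_rate:
        return record
    g = math.gcd(target_rate, record.sample_rate)
    up, down = target_rate // g, record.sample_rate // g
    samples = resample_poly(record.samples, up, down)
    return replace(record, samples=samples, sample_rate=target_rate)


def segment(record: AudioRecord, cfg: SegmentationConfig) -> list[AudioRecord]:
    """Cut a record into contiguous non-overlapping fixed-length records.

    Segments inherit the parent's label and sample rate.  The tail that
    does not fill a whole segment is dropped when ``drop_last_partial``
    is set, otherwise it is returned as a final shorter record.
    """
    if len(record) == 0:
        raise ValueError("cannot segment an empty record")
    if cfg.resample_to is not None:
        record = _resampled(record, cfg.resample_to)
    seg_len = int(round(cfg.seconds_for(record.label) * record.sample_rate))
    if seg_len <= 0:
        raise ValueError("segment length must cover at least one sample")
    out: list[AudioRecord] = []
    n_full = len(record) // seg_len
    for i in range(n_full):
        chunk = record.samples[i * seg_len : (i + 1) * seg_len]
        out.append(replace(record, samples=chunk))
    tail = record.samples[n_full * seg_len :]
    if tail.size and not cfg.drop_last_partial:
        out.append(replace(record, samples=tail))
    return out
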