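"""Mono WAV input/output (32-bit float, 16 kHz by default)."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["write_wav", "read_wav"]


def write_wav(path, samples: np.ndarray, fs: float) -> None:
    """Write a mono float32 WAV file."""
    samples = np.asarray(samples)
    if samples.ndim != 1:
        raise ValueError("only mono waveforms are written")
    wavfile.write(path, int(fs), samples.astype(np.float32))


def read_wav(path, target_fs: float | None = None) -> tuple[np.ndarray, float]:
    """Read a mono WAV as float64; optionally resample to ``target_fs``.

    Integer PCM is rescaled to [-1, 1).  Stereo input is rejected: the
    analysis chain is defined for single-channel signals.
    """
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if data.size == 0:
        raise ValueError(f"{path}: empty WAV file")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(np.float64)
    fs = float(fs)
    if target_fs is not None and target_fs != fs:
        warnings.warn(f"resampling {path} from {fs:g} Hz to {target_fs:g} Hz")
        from fractions import Fraction

        frac = Fraction(int(round(target_fs)), int(round(fs))).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator)
        fs = target_fs
    return data, fs
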