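"""Stochastic sound-texture synthesis.

A texture token is a sum of narrowband noise carriers, each multiplied by a
slowly varying non-negative modulator.  Per channel n the modulator is built
in three stages:

1. low-pass Gaussian noise x(t), spectrally shaped by W(f) = A exp(-f^2/(2 f0^2));
   the gain A sets the standard deviation of x and f0 the fluctuation rate
   (characteristic time-scale t0 = 1/f0);
2. a softplus nonlinearity a(t) = log(1 + exp(x(t) - B)), which leaves the
   modulator near zero when x is well below the offset B and linear in x far
   above it, so A and B together control modulation depth ("sparsity");
3. comodulation mixing m_n(t) = C a0(t) + (1 - C) a_n(t) between a shared
   modulator a0 and a private modulator a_n, with C in [0, 1].

A, B, f0 and C are shared by all channels of a given sound; every token is
normalized to a common root-mean-square level so that tokens differing in the
modulator statistics keep the same long-term spectrum and level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .carriers import CarrierSpec, carrier_table, generate_carrier

__all__ = [
    "TextureParams",
    "ModulatorSet",
    "TextureToken",
    "gaussian_lowpass_noise",
    "softplus_modulator",
    "mix_comodulation",
    "synthesize",
    "draw_segment",
    "DEFAULT_RMS",
    "EDGE_TRIM",
]

#: rms level of every synthesized token (arbitrary full-scale units; playback
#: level is a presentation property, not a numerical one).
DEFAULT_RMS = 0.05

#: seconds discarded at each end of a synthesized parent waveform, so that
#: AR(2) filter warm-up transients never reach the analysis stage.
EDGE_TRIM = 0.05


@dataclass(frozen=True)
class TextureParams:
    """The four generative parameters plus carrier/sampling configuration.

    A     -- modulator gain; standard deviation of the pre-nonlinearity noise.
    B     -- softplus offset (> 0); larger B makes the modulator sparser.
    f0    -- modulation-rate parameter in Hz; time-scale t0 = 1/f0.
    C     -- comodulation weight in [0, 1]; 0 = independent bands, 1 = one
             shared modulator for all bands.
    """

    A: float
    B: float
    f0: float
    C: float
    n_carriers: int = 20
    fs: float = 16000.0
    duration: float = 1.0
    seed: int = 0
    rms_target: float = DEFAULT_RMS

    def __post_init__(self) -> None:
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"comodulation C must lie in [0, 1], got {self.C}")
        if self.B <= 0:
            raise ValueError(f"softplus offset B must be > 0, got {self.B}")
        if self.A <= 0:
            raise ValueError(f"modulator gain A must be > 0, got {self.A}")
        if self.f0 <= 0:
            raise ValueError(f"modulation rate f0 must be > 0, got {self.f0}")
        table = carrier_table(self.n_carriers)
        top = table[-1]
        if top.cf + top.erb / 2.0 >= self.fs / 2.0:
            raise ValueError("highest carrier band edge exceeds Nyquist frequency")

    @property
    def carriers(self) -> list[CarrierSpec]:
        return carrier_table(self.n_carriers)

    def with_(self, **kwargs) -> "TextureParams":
        return replace(self, **kwargs)


@dataclass
class ModulatorSet:
    """Modulators of one token: pre-nonlinearity noise, private/shared/mixed."""

    x: np.ndarray          # channels x time, Gaussian
    a_private: np.ndarray  # channels x time, >= 0
    a_shared: np.ndarray   # time, >= 0
    m: np.ndarray          # channels x time, >= 0


@dataclass
class TextureToken:
    samples: np.ndarray
    params: TextureParams
    rms_target: float = DEFAULT_RMS

    @property
    def fs(self) -> float:
        return self.params.fs

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def gaussian_lowpass_noise(
    f0: float, A: float, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise with amplitude spectrum W(f) = exp(-f^2/(2 f0^2)).

    Realized in the frequency domain (multiply the DFT of white noise by W,
    symmetric in +-f) to avoid kernel-truncation error; the output is scaled
    analytically so its standard deviation equals ``A`` in expectation.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if f0 <= 0:
        raise ValueError(f"f0 must be > 0, got {f0}")
    if f0 >= fs / 2.0:
        raise ValueError(f"f0 = {f0} Hz is at or beyond Nyquist ({fs / 2} Hz)")
    white = rng.standard_normal(n_samples)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    w = np.exp(-(freqs**2) / (2.0 * f0**2))
    x = np.fft.irfft(np.fft.rfft(white) * w, n_samples)
    # variance of the filtered process: mean of |W|^2 over the two-sided grid
    w2 = w**2
    total = 2.0 * w2.sum() - w2[0] - (w2[-1] if n_samples % 2 == 0 else 0.0)
    x *= A / np.sqrt(total / n_samples)
    return x


def softplus_modulator(x: np.ndarray, B: float) -> np.ndarray:
    """a(t) = log(1 + exp(x(t) - B)), numerically stable for large |x|."""
    if B <= 0:
        raise ValueError(f"softplus offset B must be > 0, got {B}")
    return np.logaddexp(0.0, np.asarray(x) - B)


def mix_comodulation(a_private: np.ndarray, a_shared: np.ndarray, C: float) -> np.ndarray:
    """m_n(t) = C a0(t) + (1 - C) a_n(t) per channel."""
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"comodulation C must lie in [0, 1], got {C}")
    a_private = np.atleast_2d(np.asarray(a_private))
    a_shared = np.asarray(a_shared)
    if a_private.shape[-1] != a_shared.shape[-1]:
        raise ValueError("private and shared modulators differ in length")
    return C * a_shared[None, :] + (1.0 - C) * a_private


def make_modulators(
    params: TextureParams, n_samples: int, seed_seq: np.random.SeedSequence
) -> ModulatorSet:
    """Draw the shared and per-channel private modulators of one token.

    The shared modulator and each private modulator come from independent
    RNG streams spawned from the token seed, so the token is reproducible
    bit-for-bit and channels are statistically independent at C = 0.
    """
    n = params.n_carriers
    children = seed_seq.spawn(n + 1)
    shared_x = gaussian_lowpass_noise(
        params.f0, params.A, n_samples, params.fs, np.random.default_rng(children[0])
    )
    xs = np.empty((n, n_samples))
    for i in range(n):
        xs[i] = gaussian_lowpass_noise(
            params.f0, params.A, n_samples, params.fs, np.random.default_rng(children[i + 1])
        )
    a_shared = softplus_modulator(shared_x, params.B)
    a_private = softplus_modulator(xs, params.B)
    m = mix_comodulation(a_private, a_shared, params.C)
    return ModulatorSet(x=xs, a_private=a_private, a_shared=a_shared, m=m)


def synthesize(params: TextureParams, carrier_mask: np.ndarray | None = None) -> TextureToken:
    """Synthesize one texture token: sum of modulated carriers, rms-normalized.

    Modulators are generated at the full audio rate (f0 is far below fs).
    ``carrier_mask`` optionally silences individual carriers (diagnostics).
    An extra 50 ms is synthesized and discarded at each end so that filter
    warm-up never appears in the returned waveform.
    """
    fs = params.fs
    trim = int(round(EDGE_TRIM * fs))
    n = int(round(params.duration * fs)) + 2 * trim
    root = np.random.SeedSequence(params.seed)
    mod_seq, carrier_seq = root.spawn(2)
    mods = make_modulators(params, n, mod_seq)
    carrier_children = carrier_seq.spawn(params.n_carriers)
    out = np.zeros(n)
    for i, spec in enumerate(params.carriers):
        if carrier_mask is not None and not carrier_mask[i]:
            continue
        carrier = generate_carrier(spec, n, fs, np.random.default_rng(carrier_children[i]))
        out += mods.m[i] * carrier
    out = out[trim : n - trim]
    rms = np.sqrt(np.mean(out**2))
    if rms == 0:
        raise ValueError("synthesized token is silent; cannot rms-normalize")
    return TextureToken(samples=out * (params.rms_target / rms), params=params)


def draw_segment(
    token: TextureToken, seg_duration: float, rng: np.random.Generator
) -> TextureToken:
    """Contiguous random excerpt of ``seg_duration`` s, re-normalized to rms_target.

    Mirrors the experimental procedure of drawing 1-s samples at uniformly
    random onsets from a 20-s parent waveform.
    """
    n_seg = int(round(seg_duration * token.fs))
    n = len(token.samples)
    if n_seg > n:
        raise ValueError(f"segment of {seg_duration} s exceeds parent of {n / token.fs} s")
    start = int(rng.integers(0, n - n_seg + 1))
    seg = token.samples[start : start + n_seg]
    rms = np.sqrt(np.mean(seg**2))
    return TextureToken(
        samples=seg * (token.rms_target / rms),
        params=token.params.with_(duration=seg_duration),
        rms_target=token.rms_target,
    )
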