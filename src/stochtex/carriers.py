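"""Narrowband noise carriers for the texture generator.

The generator's carriers are Gaussian noise filtered by two-pole (AR(2))
resonators.  The published carrier banks place centre frequencies equally in
log frequency from 500 to 4000 Hz with bandwidths given as equivalent
rectangular bandwidths (ERBs); those (cf, ERB) tables are reproduced here
verbatim and the resonator pole radius is solved numerically so that the
realized filter's ERB,

    ERB = (integral of |H(f)|^2 df) / max |H(f)|^2,

matches the tabulated value.  The pole angle is then adjusted so that the
magnitude response peaks exactly at the tabulated centre frequency (a raw
two-pole resonator peaks slightly below its pole frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

__all__ = ["CarrierSpec", "carrier_table", "ar2_coefficients", "generate_carrier"]


@dataclass(frozen=True)
class CarrierSpec:
    """One narrowband carrier: centre frequency, ERB and Q = cf/erb (Hz, Hz, -)."""

    cf: float
    erb: float

    @property
    def q(self) -> float:
        return self.cf / self.erb


# (centre frequency Hz, ERB Hz) for the 20- and 8-carrier banks.
# Centre frequencies are equally spaced in log frequency from 500 to 4000 Hz.
_TABLE_20 = [
    (499, 122), (571, 134), (648, 147), (733, 162), (827, 177),
    (928, 194), (1042, 213), (1165, 235), (1299, 257), (1448, 282),
    (1610, 310), (1787, 340), (1984, 373), (2199, 409), (2434, 449),
    (2691, 492), (2975, 540), (3285, 593), (3626, 650), (4000, 713),
]
_TABLE_8 = [
    (499, 122), (709, 158), (976, 203), (1320, 261),
    (1762, 335), (2330, 431), (3061, 554), (4000, 713),
]


def carrier_table(n_carriers: int) -> list[CarrierSpec]:
    """Return the published carrier bank for ``n_carriers`` in {8, 20}."""
    if n_carriers == 20:
        table = _TABLE_20
    elif n_carriers == 8:
        table = _TABLE_8
    else:
        raise ValueError(f"carrier bank is defined for 8 or 20 carriers, got {n_carriers}")
    return [CarrierSpec(float(cf), float(erb)) for cf, erb in table]


def _ar2_erb(r: float, theta: float, fs: float, freqs: np.ndarray) -> float:
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    _, h = signal.freqz([1.0], a, worN=freqs, fs=fs)
    p = np.abs(h) ** 2
    return float(np.trapezoid(p, freqs) / p.max())


@lru_cache(maxsize=256)
def ar2_coefficients(cf: float, erb: float, fs: float) -> tuple[float, float, float]:
    """AR(2) resonator (a1, a2, gain) with peak at ``cf`` and realized ERB ``erb``.

    The returned gain normalizes the filter so that unit-variance white noise
    input yields unit-variance output.
    """
    if cf + erb / 2.0 >= fs / 2.0:
        raise ValueError(f"carrier band (cf={cf}, erb={erb}) exceeds Nyquist {fs / 2}")
    freqs = np.linspace(0.0, fs / 2.0, 8192)
    omega_c = 2.0 * np.pi * cf / fs
    theta = omega_c
    r = 0.9
    # Alternate: solve radius for the ERB at fixed pole angle, then move the
    # pole angle so the response peak returns to cf.  Converges in two passes.
    for _ in range(3):
        lo, hi = 0.5, 0.999999
        for _ in range(50):
            r = 0.5 * (lo + hi)
            if _ar2_erb(r, theta, fs, freqs) > erb:
                lo = r
            else:
                hi = r
        # |H| of a two-pole filter peaks where cos(w) = (1+r^2) cos(theta)/(2r);
        # invert that relation so the peak lands on cf.
        theta = float(np.arccos(np.clip(2.0 * r * np.cos(omega_c) / (1.0 + r * r), -1.0, 1.0)))
    a1 = -2.0 * r * np.cos(theta)
    a2 = r * r
    imp = signal.lfilter([1.0], [1.0, a1, a2], np.r_[1.0, np.zeros(int(20 * fs / (erb * np.pi)))])
    gain = float(np.sqrt(np.sum(imp**2)))
    return a1, a2, gain


def generate_carrier(
    spec: CarrierSpec, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance narrowband Gaussian noise centred on ``spec.cf``."""
    a1, a2, gain = ar2_coefficients(spec.cf, spec.erb, fs)
    white = rng.standard_normal(n_samples)
    return signal.lfilter([1.0 / gain], [1.0, a1, a2], white)
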