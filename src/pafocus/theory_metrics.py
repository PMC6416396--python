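"""Closed-form quantities of binary-amplitude photoacoustic wavefront shaping.

* enhancement theory for binary amplitude control of N segments over M
  independent speckle modes: η = (1/2 + (N−1)/(2π)) / M ≈ N/(2πM);
* transducer focal diameter φ = c_s·F/(f·D);
* mode count M = (D_a·φ) / (π·(d_sp/2)²) — the absorbing area inside the
  focal zone divided by the speckle-grain area;
* photoacoustic characteristic frequency f ≈ 0.66·c_s/D_a;
* the SNR metric (gated peak amplitude over the noise standard deviation
  of a signal-free reference) and the measured enhancement ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .forward_sim import Trace

__all__ = [
    "GeometrySpec",
    "EnhancementTheory",
    "enhancement_theory",
    "focal_diameter",
    "mode_count",
    "center_frequency",
    "snr",
    "enhancement_measured",
]


@dataclass(frozen=True)
class GeometrySpec:
    """Geometry of the acoustic detection, SI units throughout.

    The focal diameter may be given directly (``focal_diameter_m``) or be
    derived from (c_s, focal_length, transducer_freq, crystal_diameter).
    """

    c_s: float = 1500.0
    transducer_freq: float = 5.0e6
    absorber_diameter: float = 150.0e-6
    speckle_diameter: float = 150.0e-6
    focal_length: Optional[float] = None
    crystal_diameter: Optional[float] = None
    focal_diameter_m: Optional[float] = 880.0e-6

    def __post_init__(self) -> None:
        for name in (
            "c_s",
            "transducer_freq",
            "absorber_diameter",
            "speckle_diameter",
            "focal_length",
            "crystal_diameter",
            "focal_diameter_m",
        ):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"geometry field {name} must be positive")
        if self.focal_diameter_m is None and (
            self.focal_length is None or self.crystal_diameter is None
        ):
            raise ValueError(
                "focal diameter must be given directly or be derivable from "
                "focal_length and crystal_diameter"
            )


class EnhancementTheory(NamedTuple):
    """Exact and large-N approximate theoretical enhancement."""

    exact: float
    approx: float


def enhancement_theory(n_modes: int, m_modes: float) -> EnhancementTheory:
    """Theoretical binary-amplitude enhancement over random masks.

    exact  = (1/2 + (N−1)/(2π)) / M
    approx = N / (2π·M)

    N is the number of controllable segments, M the number of independent
    optical modes inside the absorbing area within the acoustic focus.
    """
    if n_modes < 1:
        raise ValueError("need at least one controllable segment")
    if not m_modes > 0:
        raise ValueError("mode count must be positive")
    exact = (0.5 + (n_modes - 1) / (2.0 * math.pi)) / m_modes
    approx = n_modes / (2.0 * math.pi * m_modes)
    return EnhancementTheory(exact=exact, approx=approx)


def focal_diameter(g: GeometrySpec) -> float:
    """Transducer focal diameter φ = c_s·F/(f·D) in meters."""
    if g.focal_length is None or g.crystal_diameter is None:
        raise ValueError(
            "focal_length and crystal_diameter are required to derive the "
            "focal diameter; alternatively set focal_diameter_m directly"
        )
    return g.c_s * g.focal_length / (g.transducer_freq * g.crystal_diameter)


def mode_count(g: GeometrySpec) -> float:
    """Independent optical modes in the focal zone.

    The absorbing area is the absorber diameter times the focal diameter
    (a thread crossing the focal zone); each speckle grain of diameter
    d_sp occupies π·(d_sp/2)².
    """
    phi = g.focal_diameter_m if g.focal_diameter_m is not None else focal_diameter(g)
    area = g.absorber_diameter * phi
    grain = math.pi * (g.speckle_diameter / 2.0) ** 2
    return area / grain


def center_frequency(c_s: float, d_a: float) -> float:
    """Photoacoustic characteristic frequency f = 0.66·c_s/D_a in Hz."""
    if not c_s > 0 or not d_a > 0:
        raise ValueError("speed of sound and absorber diameter must be positive")
    return 0.66 * c_s / d_a


def snr(
    trace: Trace,
    noise_std: float,
    window: Optional[Tuple[float, float]] = None,
    amplitude: str = "peak",
) -> float:
    """Signal-to-noise ratio of a trace.

    Peak absolute amplitude inside the gate (or the whole record) divided
    by the noise standard deviation measured on a signal-free (laser-off)
    reference. ``amplitude='half_p2p'`` uses half the gated peak-to-peak
    instead of the peak absolute value.
    """
    if not noise_std > 0:
        raise ValueError("SNR undefined: reference noise std must be positive")
    sel = trace.samples if window is None else trace.samples[trace.window_slice(*window)]
    if amplitude == "peak":
        amp = float(np.abs(sel).max())
    elif amplitude == "half_p2p":
        amp = float(sel.max() - sel.min()) / 2.0
    else:
        raise ValueError("amplitude must be 'peak' or 'half_p2p'")
    return amp / noise_std


def enhancement_measured(best: float, baseline: float) -> float:
    """Measured enhancement: best-mask fitness over the baseline fitness."""
    if not baseline > 0:
        raise ValueError("enhancement undefined for a non-positive baseline")
    return best / baseline
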