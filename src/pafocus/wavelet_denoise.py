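"""Discrete-wavelet denoising of single pressure traces.

Implements the VisuShrink recipe of Donoho & Johnstone: multilevel DWT
with a Daubechies-4 mother wavelet to depth 8, one global universal
threshold K = σ̂·√(2·ln M) applied to all detail coefficients (M is the
signal length), approximation coefficients untouched, inverse transform.
σ̂ is the median absolute deviation of the finest-scale detail
coefficients divided by 0.6745.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt

from .forward_sim import Trace

__all__ = [
    "WaveletConfig",
    "estimate_sigma",
    "universal_threshold",
    "denoise",
]

logger = logging.getLogger(__name__)

# MAD of a standard normal sample is Phi^-1(3/4) = 0.6745 sigma.
_MAD_TO_SIGMA = 0.6744897501960817


@dataclass(frozen=True)
class WaveletConfig:
    """Denoising parameters.

    mother         : PyWavelets wavelet name (default ``db4``).
    levels         : requested decomposition depth; capped (with a logged
                     warning) at the maximum valid depth for the trace.
    threshold_mode : ``soft`` or ``hard`` shrinkage of detail coefficients.
    sigma_estimator: ``mad`` (robust, finest-detail MAD / 0.6745) or ``std``.
    log_base       : base of the logarithm inside the universal threshold
                     (natural log by default, per Donoho's formulation).
    boundary_mode  : signal-extension mode for the DWT.
    """

    mother: str = "db4"
    levels: int = 8
    threshold_mode: str = "hard"
    sigma_estimator: str = "mad"
    log_base: float = math.e
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("decomposition depth must be at least 1")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")
        if self.sigma_estimator not in ("mad", "std"):
            raise ValueError("sigma_estimator must be 'mad' or 'std'")
        if not self.log_base > 1:
            raise ValueError("log base must exceed 1")
        pywt.Wavelet(self.mother)  # fail fast on unknown names

    def effective_levels(self, n: int) -> int:
        """Depth actually used for a length-``n`` trace."""
        max_level = pywt.dwt_max_level(n, pywt.Wavelet(self.mother).dec_len)
        if max_level < 1:
            raise ValueError(
                f"trace of length {n} is too short for wavelet '{self.mother}'"
            )
        if self.levels > max_level:
            logger.warning(
                "requested %d decomposition levels but length %d supports "
                "only %d; capping",
                self.levels,
                n,
                max_level,
            )
            return max_level
        return self.levels


def estimate_sigma(trace: Trace, cfg: WaveletConfig = WaveletConfig()) -> float:
    """Robust white-noise level estimate from the finest detail scale.

    For the default ``mad`` estimator: σ̂ = median(|d1|)/0.6745 where d1
    are the level-1 detail coefficients. Sparse transients (the pulse,
    clutter) touch few fine-scale coefficients, so the median is barely
    perturbed by them.
    """
    wavelet = pywt.Wavelet(cfg.mother)
    n = len(trace)
    if n < 2 * wavelet.dec_len:
        raise ValueError(
            f"need at least {2 * wavelet.dec_len} samples to estimate sigma, got {n}"
        )
    _, d1 = pywt.dwt(trace.samples, wavelet, mode=cfg.boundary_mode)
    if cfg.sigma_estimator == "mad":
        return float(np.median(np.abs(d1)) / _MAD_TO_SIGMA)
    return float(np.std(d1))


def universal_threshold(sigma: float, m_len: int, log_base: float = math.e) -> float:
    """Universal (VisuShrink) threshold K = σ·√(2·log m_len)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if m_len < 1:
        raise ValueError("signal length must be at least 1")
    return float(sigma * math.sqrt(2.0 * math.log(m_len) / math.log(log_base)))


def denoise(trace: Trace, cfg: WaveletConfig = WaveletConfig()) -> Trace:
    """Wavelet-threshold denoising of one trace.

    Decomposes to ``cfg.levels`` (capped to the valid maximum), shrinks
    every detail coefficient at the global universal threshold computed
    from the finest-scale σ̂, leaves the approximation untouched and
    reconstructs. Length, dt and t0 are preserved.
    """
    n = len(trace)
    levels = cfg.effective_levels(n)
    wavelet = pywt.Wavelet(cfg.mother)
    coeffs = pywt.wavedec(trace.samples, wavelet, mode=cfg.boundary_mode, level=levels)
    sigma_hat = estimate_sigma(trace, cfg)
    k = universal_threshold(sigma_hat, n, cfg.log_base)
    shrunk = [coeffs[0]] + [
        pywt.threshold(c, k, mode=cfg.threshold_mode) for c in coeffs[1:]
    ]
    rec = pywt.waverec(shrunk, wavelet, mode=cfg.boundary_mode)
    return trace.with_samples(rec[:n])
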