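"""Correlation-gated photoacoustic signal extraction and optimizer fitness.

An acquisition is accepted as a genuine photoacoustic signal only if its
denoised, time-gated waveform correlates with an adaptive reference
template above a threshold (default 0.7). The normalized correlation
coefficient

    γ_xy = Σ (x−x̄)(y−ȳ) / sqrt( Σ(x−x̄)² · Σ(y−ȳ)² )

lies in [−1, 1]; 1 is an exact waveform match. Every accepted waveform
replaces the template, tracking the slow waveform drift across
generations. Each mask's fitness is the average gated peak-to-peak value
over the accepted shots of (by default) five acquisitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .forward_sim import Mask, Trace, World, acquire, _derive_seed
from .wavelet_denoise import WaveletConfig, denoise

__all__ = [
    "Template",
    "DetectionResult",
    "FitnessOutcome",
    "ncc",
    "detect",
    "update_template",
    "fitness_single",
    "fitness_two_point",
    "initial_template",
    "default_gate",
    "DEFAULT_THRESHOLD",
    "DEFAULT_GATE_HALFWIDTH",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7
# Half-width of the acceptance gate around the expected arrival time (s).
# Wide enough that the correlation window contains the full wave-packet
# region: a transient that merely shares the band decorrelates over it.
DEFAULT_GATE_HALFWIDTH = 1.5e-6


@dataclass(frozen=True)
class Template:
    """Reference photoacoustic waveform plus acceptance settings.

    reference : the (denoised) reference trace.
    threshold : acceptance level T on the correlation coefficient.
    window    : (start_time, end_time) gate around the expected arrival.
    lag_tolerance : half-range of the lag search in seconds; ``None``
        means one period of the reference's dominant frequency.
    """

    reference: Trace
    threshold: float = DEFAULT_THRESHOLD
    window: Tuple[float, float] = (0.0, 0.0)
    lag_tolerance: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [-1, 1]")
        # validates the window against the reference span
        self.reference.window_slice(*self.window)

    def gate_slice(self, trace: Trace) -> slice:
        return trace.window_slice(*self.window)

    def lag_samples(self, dt: float) -> int:
        """Lag search half-range in samples."""
        if self.lag_tolerance is not None:
            return max(int(round(self.lag_tolerance / dt)), 0)
        ref = self.reference.samples[self.gate_slice(self.reference)]
        spec = np.abs(np.fft.rfft(ref))
        spec[0] = 0.0
        idx = int(spec.argmax())
        if idx == 0:
            return 0
        freq = idx / (ref.size * self.reference.dt)
        return max(int(round(1.0 / (freq * dt))), 0)


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of gating one acquisition against the template."""

    gamma: float
    accepted: bool
    peak_to_peak: float
    denoised: Optional[Trace] = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.gamma <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient must lie in [-1, 1]")
        if self.peak_to_peak < 0:
            raise ValueError("peak-to-peak must be nonnegative")


def ncc(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized correlation coefficient of two equal-length windows.

    Invariant to positive affine rescaling of either argument; raises on
    constant windows, where γ is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("ncc needs two equal-length 1-D windows of length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("correlation undefined for a constant window")
    return float((dx @ dy) / math.sqrt(vx * vy))


def _max_lag_ncc(x: np.ndarray, trace: Trace, gate: slice, max_lag: int) -> float:
    """Max of γ over integer lags of the gate within ±max_lag samples.

    The reference window ``x`` stays fixed; the trace window slides.
    Vectorized over lags via a strided window matrix.
    """
    n = x.size
    samples = trace.samples
    lags = []
    for lag in range(-max_lag, max_lag + 1):
        lo = gate.start + lag
        if lo < 0 or lo + n > samples.size:
            continue
        lags.append(lo)
    if not lags:
        raise ValueError("lag search window exceeds the trace span")
    windows = np.lib.stride_tricks.sliding_window_view(samples, n)[lags]
    dx = x - x.mean()
    vx = float(dx @ dx)
    if vx == 0.0:
        raise ValueError("correlation undefined for a constant template window")
    dyc = windows - windows.mean(axis=1, keepdims=True)
    vy = np.einsum("ij,ij->i", dyc, dyc)
    num = dyc @ dx
    valid = vy > 0.0
    if not valid.any():
        raise ValueError("correlation undefined for a constant signal window")
    gammas = num[valid] / np.sqrt(vx * vy[valid])
    return float(gammas.max())


def detect(
    trace: Trace,
    template: Template,
    cfg: WaveletConfig = WaveletConfig(),
) -> DetectionResult:
    """Denoise, gate and correlate one acquisition against the template.

    γ is the maximum normalized correlation over integer lags within the
    template's lag tolerance (absorbing sampling jitter); the acquisition
    is accepted iff γ ≥ threshold. Peak-to-peak is measured inside the
    gate of the denoised trace only, so clutter outside the gate cannot
    inflate the fitness.
    """
    dn = denoise(trace, cfg)
    ref_window = template.reference.samples[template.gate_slice(template.reference)]
    gate = template.gate_slice(dn)
    if ref_window.size != gate.stop - gate.start:
        raise ValueError("template and trace gates cover different sample counts")
    max_lag = template.lag_samples(dn.dt)
    gamma = _max_lag_ncc(ref_window, dn, gate, max_lag)
    gamma = min(max(gamma, -1.0), 1.0)
    gated = dn.samples[gate]
    p2p = float(gated.max() - gated.min())
    return DetectionResult(
        gamma=gamma,
        accepted=bool(gamma >= template.threshold),
        peak_to_peak=p2p,
        denoised=dn,
    )


def update_template(
    template: Template, accepted: Trace, result: Optional[DetectionResult] = None
) -> Template:
    """Replace the template reference with an accepted denoised waveform.

    The previous reference is discarded; threshold, window and lag
    tolerance are unchanged. If the detection result is supplied, updating
    from a rejected acquisition raises.
    """
    if result is not None and not result.accepted:
        raise ValueError("cannot update the template from a rejected acquisition")
    return replace(template, reference=accepted)


def _detect_or_reject(
    trace: Trace, template: Template, cfg: WaveletConfig
) -> DetectionResult:
    """detect(), but a zero-variance (signal-free) gate counts as a rejection.

    A noise-free acquisition under an all-off mask has a constant gate
    window; inside the optimization loop that is simply "no photoacoustic
    signal", not an error.
    """
    try:
        return detect(trace, template, cfg)
    except ValueError as exc:
        if "constant" in str(exc):
            return DetectionResult(gamma=0.0, accepted=False, peak_to_peak=0.0)
        raise


@dataclass(frozen=True)
class FitnessOutcome:
    """Fitness of one mask plus the side effects of measuring it."""

    fitness: float
    template: Template
    detections: Tuple[DetectionResult, ...]

    def __float__(self) -> float:
        return self.fitness


def fitness_single(
    mask: Mask,
    world: World,
    template: Template,
    n_acq: int = 5,
    seed: int = 0,
    cfg: WaveletConfig = WaveletConfig(),
) -> FitnessOutcome:
    """Average gated peak-to-peak over the accepted shots of n_acq acquisitions.

    Each accepted shot replaces the template (last accepted wins). If every
    shot is rejected the fitness is 0 and a warning is logged — a value,
    not an error.
    """
    if n_acq < 1:
        raise ValueError("need at least one acquisition per mask")
    accepted_p2p = []
    detections = []
    for i in range(n_acq):
        trace = acquire(mask, world, _derive_seed(seed, i))
        res = _detect_or_reject(trace, template, cfg)
        detections.append(res)
        if res.accepted:
            accepted_p2p.append(res.peak_to_peak)
            template = update_template(template, res.denoised, res)
    if not accepted_p2p:
        logger.warning("all %d acquisitions rejected for this mask; fitness 0", n_acq)
        fitness = 0.0
    else:
        fitness = float(np.mean(accepted_p2p))
    return FitnessOutcome(
        fitness=fitness, template=template, detections=tuple(detections)
    )


def fitness_two_point(
    mask: Mask,
    world: World,
    templates: Sequence[Template],
    n_acq: int = 5,
    seed: int = 0,
    cfg: WaveletConfig = WaveletConfig(),
) -> Tuple[float, Tuple[Template, ...], Tuple[float, ...]]:
    """Two-point fitness √(P₁·P₂) from disjoint per-absorber gates.

    Each acquisition is gated independently per absorber; Pᵢ is the
    accepted-average peak-to-peak within gate i. Returns the combined
    fitness, the updated templates and the per-gate averages.
    """
    templates = list(templates)
    if len(templates) != 2:
        raise ValueError("two-point fitness needs exactly two templates")
    (a0, b0), (a1, b1) = templates[0].window, templates[1].window
    if a0 < b1 and a1 < b0:
        raise ValueError(
            f"gates [{a0}, {b0}] and [{a1}, {b1}] overlap: "
            "peak-to-peak attribution would be ambiguous"
        )
    per_gate: list[list[float]] = [[], []]
    for i in range(n_acq):
        trace = acquire(mask, world, _derive_seed(seed, i))
        for g, template in enumerate(templates):
            res = _detect_or_reject(trace, template, cfg)
            if res.accepted:
                per_gate[g].append(res.peak_to_peak)
                templates[g] = update_template(template, res.denoised, res)
    p = tuple(float(np.mean(v)) if v else 0.0 for v in per_gate)
    return math.sqrt(p[0] * p[1]), tuple(templates), p


def default_gate(
    world: World, absorber_index: int = 0, halfwidth: float = DEFAULT_GATE_HALFWIDTH
) -> Tuple[float, float]:
    """Time gate centred on an absorber's expected arrival."""
    ta = world.absorbers[absorber_index].arrival_time
    return (ta - halfwidth, ta + halfwidth)


def initial_template(
    world: World,
    threshold: float = DEFAULT_THRESHOLD,
    repeats: int = 16,
    seed: int = 0,
    cfg: WaveletConfig = WaveletConfig(),
    absorber_index: int = 0,
    halfwidth: float = DEFAULT_GATE_HALFWIDTH,
) -> Template:
    """Template from an all-segments-open measurement at elevated averaging.

    Averages ``repeats`` all-on acquisitions before denoising, emulating
    the initial reference the closed loop starts from.
    """
    mask = Mask.all_on(world.n_segments)
    acc = np.zeros(world.n_samples)
    for i in range(repeats):
        acc += acquire(mask, world, _derive_seed(seed, 7001, i)).samples
    mean_trace = Trace(acc / repeats, dt=world.dt, t0=0.0)
    reference = denoise(mean_trace, cfg)
    return Template(
        reference=reference,
        threshold=threshold,
        window=default_gate(world, absorber_index, halfwidth),
    )
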