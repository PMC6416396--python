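"""Forward model for photoacoustic-feedback wavefront shaping.

Simulates the physics between a binary DMD segment mask and the noisy
pressure trace an oscilloscope would record:

1.  fully developed speckle behind the scatterer, modelled by an i.i.d.
    circular complex Gaussian transmission matrix from the N controllable
    segments to the M independent optical modes on the absorber;
2.  photoacoustic source amplitude ``s = Γ · μ_a · φ`` where the fluence
    ``φ`` is the summed speckle intensity over the modes inside the
    transducer focal zone;
3.  a band-limited bipolar ("N-shaped") pressure pulse at the absorber's
    characteristic frequency ``f ≈ 0.66 c_s / D_a``, shaped by the
    transducer passband;
4.  additive white Gaussian noise and transient band-limited clutter
    bursts at random record positions.

All randomness flows through explicit integer seeds so that a simulated
acquisition is bit-reproducible.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GeometryError",
    "Trace",
    "TransmissionMatrix",
    "Mask",
    "AbsorberSpec",
    "TransducerSpec",
    "NoiseSpec",
    "World",
    "sample_transmission_matrix",
    "speckle_intensities",
    "pa_amplitude",
    "synthesize_waveform",
    "unit_pulse",
    "add_noise",
    "add_clutter",
    "acquire",
    "make_default_world",
    "DEFAULT_SPEED_OF_SOUND",
    "DEFAULT_N_SEGMENTS",
    "DEFAULT_M_MODES",
    "DEFAULT_PRE_DENOISE_SNR",
]

# Speed of sound in water; reproduces the 6.6 MHz characteristic frequency
# of a 150 um absorber exactly.
DEFAULT_SPEED_OF_SOUND = 1500.0  # m/s

# 32 x 18 DMD segment grid.
DEFAULT_N_SEGMENTS = 576
# Nearest integer to the 7.47 independent optical modes inside the focal zone.
DEFAULT_M_MODES = 7

# Average single-shot SNR of the unprocessed photoacoustic signal under
# random masks; the default white-noise level is calibrated to this.
DEFAULT_PRE_DENOISE_SNR = 3.86


class GeometryError(ValueError):
    """Invalid simulation geometry (dimensions, sampling, mask length)."""


def _derive_seed(*entropy: int) -> int:
    """Deterministically fold integers into a single 32-bit seed."""
    return int(np.random.SeedSequence([int(e) for e in entropy]).generate_state(1)[0])


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled 1-D pressure record.

    Parameters
    ----------
    samples : array-like of float
        Pressure values in arbitrary units.
    dt : float
        Sampling interval in seconds (> 0).
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("trace needs a non-empty 1-D sample vector")
        if not self.dt > 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample time stamps in seconds."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def with_samples(self, samples: np.ndarray) -> "Trace":
        """A copy of this trace with new samples and identical time metadata."""
        return Trace(samples=np.asarray(samples, dtype=float), dt=self.dt, t0=self.t0)

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Index slice covering the closed time interval [t_start, t_end]."""
        if t_end <= t_start:
            raise ValueError("window end must exceed window start")
        lo = int(math.ceil((t_start - self.t0) / self.dt - 1e-9))
        hi = int(math.floor((t_end - self.t0) / self.dt + 1e-9)) + 1
        lo = max(lo, 0)
        hi = min(hi, self.samples.size)
        if hi <= lo:
            raise ValueError(
                f"window [{t_start}, {t_end}] s lies outside the trace span"
            )
        return slice(lo, hi)


@dataclass(frozen=True)
class TransmissionMatrix:
    """Complex scattering coupling from N segments to M speckle modes."""

    entries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=complex)
        if entries.ndim != 2 or entries.shape[0] < 1 or entries.shape[1] < 1:
            raise GeometryError("transmission matrix must be 2-D and non-empty")
        object.__setattr__(self, "entries", entries)

    @property
    def m_modes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_segments(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class Mask:
    """Binary on/off pattern over the N DMD segments."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1 or bits.size < 1:
            raise ValueError("mask must be a non-empty 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("mask elements must all be 0 or 1")
        object.__setattr__(self, "bits", bits.astype(np.uint8))

    def __len__(self) -> int:
        return self.bits.size

    @property
    def open_fraction(self) -> float:
        return float(self.bits.mean())

    @classmethod
    def all_on(cls, n_segments: int) -> "Mask":
        return cls(np.ones(n_segments, dtype=np.uint8))

    @classmethod
    def all_off(cls, n_segments: int) -> "Mask":
        return cls(np.zeros(n_segments, dtype=np.uint8))

    @classmethod
    def random(cls, n_segments: int, rng: np.random.Generator) -> "Mask":
        """Bernoulli(1/2) random mask."""
        return cls(rng.integers(0, 2, size=n_segments, dtype=np.uint8))


@dataclass(frozen=True)
class AbsorberSpec:
    """Optical absorber generating the photoacoustic source.

    grueneisen : Grüneisen parameter Γ (dimensionless thermoelastic efficiency).
    mu_a       : optical absorption coefficient μ_a (1/m).
    diameter   : absorber diameter D_a (m); sets the pulse's characteristic
                 frequency f ≈ 0.66·c_s/D_a.
    arrival_time : acoustic time of flight from absorber to transducer (s).
    """

    grueneisen: float
    mu_a: float
    diameter: float
    arrival_time: float

    def __post_init__(self) -> None:
        for name in ("grueneisen", "mu_a", "diameter", "arrival_time"):
            if not getattr(self, name) > 0:
                raise ValueError(f"absorber {name} must be positive")

    def center_frequency(self, c_s: float) -> float:
        """Characteristic photoacoustic frequency 0.66·c_s/D_a in Hz."""
        return 0.66 * c_s / self.diameter


@dataclass(frozen=True)
class TransducerSpec:
    """Receiving ultrasound transducer.

    The passband is flat over ``center_freq · (1 ± fractional_bandwidth/2)``
    with Gaussian roll-off outside, so a pulse whose characteristic
    frequency lies inside the band keeps its spectral peak.
    """

    center_freq: float
    fractional_bandwidth: float = 0.8
    focal_length: Optional[float] = None
    crystal_diameter: Optional[float] = None
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if not self.center_freq > 0:
            raise ValueError("transducer center frequency must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional bandwidth must lie in (0, 2)")

    @property
    def passband(self) -> Tuple[float, float]:
        """Flat-response band edges (Hz)."""
        half = 0.5 * self.fractional_bandwidth * self.center_freq
        return (self.center_freq - half, self.center_freq + half)

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Magnitude response: flat in-band, Gaussian skirts outside."""
        lo, hi = self.passband
        sigma = 0.25 * self.fractional_bandwidth * self.center_freq
        f = np.abs(np.asarray(freqs, dtype=float))
        out = np.ones_like(f)
        below = f < lo
        above = f > hi
        out[below] = np.exp(-0.5 * ((f[below] - lo) / sigma) ** 2)
        out[above] = np.exp(-0.5 * ((f[above] - hi) / sigma) ** 2)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances of one oscilloscope acquisition.

    sigma        : white Gaussian noise level σ (pressure units).
    clutter_rate : expected number of transient clutter bursts per record.
    clutter_amp  : clutter peak-amplitude scale (pressure units).
    seed         : base seed for the white-noise stream.
    clutter_seed : base seed for the clutter stream (defaults to ``seed``),
                   so clutter can be re-randomized independently of noise.
    clutter_band : overall frequency extent (Hz) of the bursts; broadband,
                   covering the photoacoustic band.
    clutter_peak_freq : frequency (Hz) of the spectral peak the bursts
                   carry on top of the broadband floor, inside the
                   transducer passband — so band-pass filtering cannot
                   remove them.
    clutter_duration : burst envelope duration (s).
    adc_levels   : optional number of uniform quantization levels emulating
                   the oscilloscope ADC (None disables quantization).
    """

    sigma: float
    clutter_rate: float = 0.0
    clutter_amp: float = 0.0
    seed: int = 0
    clutter_seed: Optional[int] = None
    clutter_band: Tuple[float, float] = (1.5e6, 25.0e6)
    clutter_peak_freq: float = 5.5e6
    clutter_duration: float = 2.0e-6
    adc_levels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.clutter_rate < 0:
            raise ValueError("clutter rate must be nonnegative")
        if self.clutter_band[0] <= 0 or self.clutter_band[1] <= self.clutter_band[0]:
            raise ValueError("clutter band must be a positive interval")

    @property
    def effective_clutter_seed(self) -> int:
        return self.seed if self.clutter_seed is None else self.clutter_seed


@dataclass(frozen=True)
class World:
    """Everything the simulated experiment needs for one acquisition.

    With several absorbers the transmission-matrix rows are split into
    equal contiguous blocks, one block of speckle modes per absorber
    (distinct absorbers sit in distinct speckle regions).
    """

    tm: TransmissionMatrix
    absorbers: Tuple[AbsorberSpec, ...]
    transducer: TransducerSpec
    noise: NoiseSpec
    c_s: float = DEFAULT_SPEED_OF_SOUND
    dt: float = 4.0e-9
    n_samples: int = 4096
    sensitivities: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if isinstance(self.absorbers, AbsorberSpec):
            object.__setattr__(self, "absorbers", (self.absorbers,))
        else:
            object.__setattr__(self, "absorbers", tuple(self.absorbers))
        if len(self.absorbers) < 1:
            raise GeometryError("world needs at least one absorber")
        if self.tm.m_modes % len(self.absorbers) != 0:
            raise GeometryError(
                "transmission-matrix mode count must divide evenly over absorbers"
            )
        if self.sensitivities is not None:
            sens = tuple(float(s) for s in self.sensitivities)
            if len(sens) != len(self.absorbers):
                raise GeometryError("one sensitivity per absorber required")
            object.__setattr__(self, "sensitivities", sens)
        if not self.c_s > 0 or not self.dt > 0 or self.n_samples < 1:
            raise GeometryError("c_s, dt must be positive and n_samples >= 1")

    @property
    def n_segments(self) -> int:
        return self.tm.n_segments

    def sensitivity(self, i: int) -> float:
        if self.sensitivities is not None:
            return self.sensitivities[i]
        return self.transducer.sensitivity

    def mode_rows(self, i: int) -> slice:
        """Row block of the transmission matrix feeding absorber ``i``."""
        per = self.tm.m_modes // len(self.absorbers)
        return slice(i * per, (i + 1) * per)


# --------------------------------------------------------------------------
# Speckle and photoacoustic source
# --------------------------------------------------------------------------


def sample_transmission_matrix(
    m_modes: int, n_segments: int, seed: int
) -> TransmissionMatrix:
    """Draw an i.i.d. circular complex Gaussian transmission matrix.

    Entries have zero mean and unit variance (1/2 per real component),
    the standard fully-developed-speckle model. Deterministic given
    ``seed``.
    """
    if m_modes < 1 or n_segments < 1:
        raise GeometryError(
            f"matrix dimensions must be positive, got {m_modes}x{n_segments}"
        )
    rng = np.random.default_rng(seed)
    re = rng.standard_normal((m_modes, n_segments))
    im = rng.standard_normal((m_modes, n_segments))
    entries = (re + 1j * im) / math.sqrt(2.0)
    return TransmissionMatrix(entries=entries, seed=int(seed))


def speckle_intensities(tm: TransmissionMatrix, mask: Mask) -> np.ndarray:
    """Per-mode speckle intensity I_m = |Σ_n t_mn b_n|² under a mask."""
    if len(mask) != tm.n_segments:
        raise GeometryError(
            f"mask length {len(mask)} does not match {tm.n_segments} segments"
        )
    field = tm.entries @ mask.bits.astype(float)
    return np.abs(field) ** 2


def pa_amplitude(
    intensities: np.ndarray,
    absorber: AbsorberSpec,
    sensitivity: float = 1.0,
) -> float:
    """Photoacoustic source amplitude s = sensitivity · Γ · μ_a · Σ_m I_m."""
    intensities = np.asarray(intensities, dtype=float)
    if (intensities < 0).any():
        raise ValueError("speckle intensities must be nonnegative")
    return float(sensitivity * absorber.grueneisen * absorber.mu_a * intensities.sum())


# --------------------------------------------------------------------------
# Waveform synthesis
# --------------------------------------------------------------------------


@functools.lru_cache(maxsize=64)
def _unit_pulse_samples(
    f_pulse: float,
    arrival_time: float,
    fc: float,
    bw: float,
    dt: float,
    n_samples: int,
) -> np.ndarray:
    """Unit-peak band-limited bipolar pulse; cached because the GA reuses it.

    Time-domain seed is a differentiated Gaussian with spectral peak at
    ``f_pulse`` (τ = 1/(2π f_pulse)); the transducer passband is applied
    in the frequency domain.
    """
    tau = 1.0 / (2.0 * math.pi * f_pulse)
    t = dt * np.arange(n_samples) - arrival_time
    raw = -(t / tau) * np.exp(-0.5 * (t / tau) ** 2)
    spec = np.fft.rfft(raw)
    freqs = np.fft.rfftfreq(n_samples, d=dt)
    tr = TransducerSpec(center_freq=fc, fractional_bandwidth=bw)
    shaped = np.fft.irfft(spec * tr.response(freqs), n=n_samples)
    peak = np.abs(shaped).max()
    if peak == 0.0:
        return shaped
    out = shaped / peak
    out.setflags(write=False)
    return out


def unit_pulse(
    absorber: AbsorberSpec,
    transducer: TransducerSpec,
    c_s: float,
    dt: float,
    n_samples: int,
) -> np.ndarray:
    """The unit-peak received pulse shape for this absorber/transducer pair."""
    f_pulse = absorber.center_frequency(c_s)
    if not dt < 1.0 / (4.0 * f_pulse):
        raise GeometryError(
            f"dt={dt:g} s undersamples the {f_pulse / 1e6:.2f} MHz pulse; "
            f"need dt < {1.0 / (4.0 * f_pulse):g} s"
        )
    return _unit_pulse_samples(
        f_pulse,
        absorber.arrival_time,
        transducer.center_freq,
        transducer.fractional_bandwidth,
        dt,
        int(n_samples),
    )


def synthesize_waveform(
    amplitude: float,
    absorber: AbsorberSpec,
    transducer: TransducerSpec,
    c_s: float,
    dt: float,
    n_samples: int,
) -> Trace:
    """Noise-free received pressure trace for a given source amplitude.

    The pulse is bipolar and zero-mean, centred at ``absorber.arrival_time``,
    its magnitude-spectrum peak at 0.66·c_s/D_a (band-limited by the
    transducer), and its peak absolute value equals ``amplitude`` exactly,
    so peak-to-peak scales linearly with the source strength.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    pulse = unit_pulse(absorber, transducer, c_s, dt, n_samples)
    return Trace(samples=amplitude * pulse, dt=dt, t0=0.0)


# --------------------------------------------------------------------------
# Noise and clutter
# --------------------------------------------------------------------------


def add_noise(trace: Trace, noise: NoiseSpec) -> Trace:
    """Add white Gaussian noise σ·N(0,1) per sample; σ=0 is the identity."""
    if noise.sigma == 0.0:
        return trace
    rng = np.random.default_rng(noise.seed)
    out = trace.samples + noise.sigma * rng.standard_normal(trace.samples.size)
    return trace.with_samples(out)


def clutter_burst(
    n_samples: int,
    dt: float,
    center: float,
    noise: NoiseSpec,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> np.ndarray:
    """One unit-peak transient clutter burst on the record's time grid.

    Emulates electrostatic/amplifier transients: a Hann-windowed burst of
    filtered noise whose spectrum has a broadband floor over
    ``clutter_band`` plus a peak at ``clutter_peak_freq`` inside the
    transducer passband — the same frequency components as the
    photoacoustic signal, hence immune to band-pass filtering.
    """
    raw = rng.standard_normal(n_samples)
    spec = np.fft.rfft(raw)
    freqs = np.fft.rfftfreq(n_samples, d=dt)
    lo, hi = noise.clutter_band
    skirt = 2.0e6
    resp = 0.5 * np.ones_like(freqs)
    below = freqs < lo
    above = freqs > hi
    resp[below] = 0.5 * np.exp(-0.5 * ((freqs[below] - lo) / skirt) ** 2)
    resp[above] = 0.5 * np.exp(-0.5 * ((freqs[above] - hi) / skirt) ** 2)
    resp += 0.25 * np.exp(-0.5 * ((freqs - noise.clutter_peak_freq) / 1.5e6) ** 2)
    filtered = np.fft.irfft(spec * resp, n=n_samples)
    t = t0 + dt * np.arange(n_samples)
    rel = (t - center) / noise.clutter_duration
    envelope = np.where(
        (rel >= -0.5) & (rel <= 0.5), 0.5 * (1.0 + np.cos(2.0 * math.pi * rel)), 0.0
    )
    burst = filtered * envelope
    peak = np.abs(burst).max()
    return burst / peak if peak > 0 else burst


def add_clutter(trace: Trace, noise: NoiseSpec) -> Trace:
    """Superimpose Poisson(clutter_rate) transient clutter bursts.

    Burst centres are uniform over the record and peak amplitudes are
    clutter_amp scaled by U(0.5, 1.5). clutter_rate=0 is the identity;
    successive seeds put the bursts at different positions.
    """
    if noise.clutter_rate == 0.0:
        return trace
    rng = np.random.default_rng(noise.effective_clutter_seed)
    count = int(rng.poisson(noise.clutter_rate))
    if count == 0:
        return trace
    out = trace.samples.copy()
    for _ in range(count):
        center = float(rng.uniform(trace.t0, trace.t0 + trace.duration))
        amp = noise.clutter_amp * float(rng.uniform(0.5, 1.5))
        out += amp * clutter_burst(
            trace.samples.size, trace.dt, center, noise, rng, trace.t0
        )
    return trace.with_samples(out)


def _quantize(trace: Trace, noise: NoiseSpec) -> Trace:
    """Uniform ADC quantization over the observed range (off by default)."""
    if noise.adc_levels is None:
        return trace
    levels = int(noise.adc_levels)
    if levels < 2:
        raise ValueError("adc_levels must be at least 2")
    lo = trace.samples.min()
    hi = trace.samples.max()
    if hi == lo:
        return trace
    step = (hi - lo) / (levels - 1)
    out = lo + step * np.round((trace.samples - lo) / step)
    return trace.with_samples(out)


# --------------------------------------------------------------------------
# One oscilloscope shot
# --------------------------------------------------------------------------


def acquire(mask: Mask, world: World, seed: int) -> Trace:
    """Simulate one oscilloscope acquisition under a mask.

    Sums the synthesized waveform of every absorber (each driven by its own
    block of speckle modes, arrival time and sensitivity), then adds white
    noise and clutter. Noise and clutter streams get independent seeds
    derived from ``(spec seed, acquisition seed)``, so re-seeding the
    clutter stream alone leaves the white noise untouched.
    """
    signal = np.zeros(world.n_samples)
    for i, absorber in enumerate(world.absorbers):
        intensities = speckle_intensities(
            TransmissionMatrix(world.tm.entries[world.mode_rows(i)], world.tm.seed),
            mask,
        )
        amp = pa_amplitude(intensities, absorber, world.sensitivity(i))
        wf = synthesize_waveform(
            amp, absorber, world.transducer, world.c_s, world.dt, world.n_samples
        )
        signal = signal + wf.samples
    trace = Trace(samples=signal, dt=world.dt, t0=0.0)
    shot_noise = replace(
        world.noise,
        seed=_derive_seed(world.noise.seed, seed, 0),
        clutter_seed=_derive_seed(world.noise.effective_clutter_seed, seed, 1),
    )
    trace = add_noise(trace, shot_noise)
    trace = add_clutter(trace, shot_noise)
    trace = _quantize(trace, shot_noise)
    return trace


# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------


def make_default_world(
    seed: int = 0,
    n_segments: int = DEFAULT_N_SEGMENTS,
    m_modes: int = DEFAULT_M_MODES,
    sigma: Optional[float] = None,
    clutter_rate: float = 0.8,
    two_point: bool = False,
    dt: float = 4.0e-9,
    n_samples: int = 4096,
) -> World:
    """The default simulated experiment.

    A 150 μm absorber insonified through a 32×18-segment DMD, received by a
    5 MHz / 80%-bandwidth transducer at 4 ns sampling over a 16.4 μs record.
    Γ·μ_a is scaled so the expected random-mask source amplitude equals
    M·N/2 intensity units; the default white-noise σ is calibrated so the
    expected unprocessed single-shot SNR is 3.86, and the clutter peak
    amplitude is 0.35× the expected photoacoustic peak.

    ``two_point=True`` yields two identical 150 μm absorbers 500 μm apart
    along the acoustic axis, sharing the mode budget equally.
    """
    n_absorbers = 2 if two_point else 1
    tm = sample_transmission_matrix(m_modes * n_absorbers, n_segments, seed)
    base_arrival = 8.0e-6
    spacing_delay = 500.0e-6 / DEFAULT_SPEED_OF_SOUND  # 500 um apart on-axis
    absorbers = tuple(
        AbsorberSpec(
            grueneisen=0.2,
            mu_a=5.0,
            diameter=150.0e-6,
            arrival_time=base_arrival + i * spacing_delay,
        )
        for i in range(n_absorbers)
    )
    # Expected random-mask amplitude per absorber: Γ·μ_a·M·N/2 = M·N/2 here.
    expected_amp = 1.0 * m_modes * n_segments / 2.0
    if sigma is None:
        sigma = expected_amp / DEFAULT_PRE_DENOISE_SNR
    noise = NoiseSpec(
        sigma=float(sigma),
        clutter_rate=float(clutter_rate),
        clutter_amp=0.35 * float(expected_amp),
        seed=_derive_seed(seed, 1),
    )
    transducer = TransducerSpec(center_freq=5.0e6, fractional_bandwidth=0.8)
    return World(
        tm=tm,
        absorbers=absorbers,
        transducer=transducer,
        noise=noise,
        c_s=DEFAULT_SPEED_OF_SOUND,
        dt=dt,
        n_samples=n_samples,
    )
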