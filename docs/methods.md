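# Methods

This note records the models behind `pafocus`, the defaults and why they
were chosen, and what the simulation does and does not capture.

## Forward model

**Speckle.** The scattering medium is a transmission matrix `T` with
i.i.d. circular complex Gaussian entries (zero mean, unit variance) from
the N DMD segments to the M optical modes on the absorber — the standard
fully-developed-speckle model, and the assumption under which the
binary-amplitude enhancement theory `η = (1/2 + (N−1)/2π)/M` holds. Mode
m's intensity under a binary mask `b` is `I_m = |Σ_n t_mn b_n|²`, so
per-mode intensities are exponentially distributed and the all-open mask
has twice the mean intensity of Bernoulli(½) masks. Defaults: N = 576
(a 32×18 segment grid) and M = 7 (the integer closest to the 7.47 modes
that the default geometry implies; the theory module keeps the
non-integer value).

**Photoacoustic source.** The source amplitude is
`s = sensitivity · Γ · μ_a · Σ_m I_m` with Γ the Grüneisen parameter and
μ_a the absorption coefficient (defaults Γ = 0.2, μ_a = 5 — pressure
units are arbitrary, only ratios matter). Each absorber owns an equal
block of transmission-matrix rows: distinct absorbers sit in distinct
speckle regions.

**Received pulse.** A point-like absorber of diameter `D_a` radiates a
bipolar ("N-shaped") transient with characteristic frequency
`f ≈ 0.66·c_s/D_a`; with `c_s = 1500 m/s` (water) and `D_a = 150 μm`
that is 6.6 MHz. The pulse is synthesized as a differentiated Gaussian
with `τ = 1/(2πf)` (its spectral peak falls exactly at `f`), then shaped
by the transducer response: flat over `f_c(1 ± bw/2)` with Gaussian
skirts (defaults `f_c = 5 MHz`, `bw = 0.8`), modelling a transducer
"whose bandwidth covers" the pulse band — the spectral peak therefore
stays at 6.6 MHz. The unit pulse is normalized to unit peak, so source
amplitude, gated peak and peak-to-peak scale exactly linearly.
Synthesis refuses sampling intervals coarser than a quarter period.
A consequence of the ~4 MHz bandwidth is ringing on a ~250 ns scale:
two absorbers 500 μm (333 ns) apart leak a few percent of peak-to-peak
into each other's gates, so gate isolation is approximate by physics,
not by implementation.

**Noise.** White Gaussian noise `σ·ω`, `ω ~ N(0,1)` per sample. The
default σ is calibrated so that the expected unprocessed single-shot SNR
under random masks equals 3.86, the regime the method is designed for.
Optional uniform ADC quantization is off by default.

**Clutter.** Electrostatic/amplifier transients are modelled as
Hann-enveloped bursts of filtered noise, 2 μs long, Poisson-distributed
(rate 0.8 per record) at uniform record positions, with peak amplitude
0.35× the expected photoacoustic peak (per burst scaled by U(0.5, 1.5)).
Their spectrum has a broadband floor over 1.5–25 MHz plus a peak at
5.5 MHz inside the transducer passband, so they genuinely share the
signal band and band-pass filtering cannot remove them. The real
experiment characterizes clutter only qualitatively; these parameters
were fixed to reproduce its two reported detection statistics —
photoacoustic acquisitions correlate γ > 0.8 with the template while
clutter-only windows fall below 0.4 — and were frozen before the test
suite was written. Short coherent tone bursts were rejected as a model:
against a short band-limited template any in-band tone correlates far
too well (γ ≈ 0.5–0.9 at the best lag), contradicting the reported
statistics.

Every acquisition's noise and clutter streams are seeded independently
(derived from the spec seed and the shot seed), so clutter can be
re-randomized without touching the white noise, and any run replays
bit-identically.

## Wavelet denoising

Multilevel DWT, Daubechies-4, depth 8 (capped with a warning for short
records), symmetric boundary extension; one global universal threshold
`K = σ̂·√(2·ln M)` (natural log; M the record length) applied to all
detail levels; approximation coefficients untouched. `σ̂` is
`median(|d₁|)/0.6745` over the finest detail coefficients — robust to
the sparse pulse and to clutter.

**Hard thresholding is the default** (soft is selectable). At the
operating point the method targets — unprocessed SNR 3.86 on a 2048-
sample record — the universal threshold `K ≈ 3.9σ` is comparable to the
largest pulse coefficients themselves; soft thresholding subtracts K
from each surviving coefficient and erodes the recovered peak enough
that the median post-denoising SNR stays near 22, short of the ~25
level the method is known to reach, while hard thresholding keeps the
surviving coefficients intact and reaches median SNR ≈ 40+. The
residual noise floor after either mode is dominated by the untouched
level-8 approximation (≈ σ·√(n_approx/M)).

SNR is measured as the gated peak absolute amplitude divided by the
standard deviation of a signal-free (laser-off) reference record passed
through the same pipeline; half-peak-to-peak is selectable.

## Correlation gating

The γ statistic is the textbook normalized correlation coefficient over
the gate window, maximized over integer lags within ± one pulse period
(estimated from the template's dominant frequency) to absorb sampling
jitter. The gate is centred on the expected arrival with default
half-width 1.5 μs: wide enough to contain the full wave packet region,
which matters for specificity — the correlation's power to reject an
in-band transient grows with the number of independent samples in the
window. Acceptance threshold T = 0.7. Peak-to-peak is evaluated inside
the gate only, so clutter elsewhere in the record cannot inflate the
fitness. Each accepted waveform replaces the template (last accepted
wins within a mask's five shots); the initial template is measured with
all segments open at 16-shot averaging. A mask whose five shots are all
rejected scores fitness 0 (logged), not an error; a degenerate
zero-variance gate (e.g. an all-off mask in a noise-free world) counts
as a rejection inside the loop, while the standalone `ncc`/`detect`
calls raise on it. For two-point focusing each absorber has its own
disjoint gate and template; the fitness is `√(P₁·P₂)`.

Whether the five-shot average should include rejected shots as zeros is
not specified by the experiment's description; this implementation
averages over accepted shots only, which keeps the fitness an unbiased
amplitude estimate rather than mixing in the rejection rate.

## Genetic algorithm

Defaults: 50 masks × 80 generations, five gated acquisitions per mask.
Selection is linear rank-proportional (ties share averaged weights, so
equal fitnesses are drawn uniformly); tournament selection is available.
Uniform crossover at rate 0.9, per-bit mutation at 0.005, elitism 2 —
operator rates are engineering choices tuned for convergence within the
80×50 evaluation budget on the N = 576 / M = 7 benchmark. Identical
masks are re-measured rather than cached, as in the physical experiment.
With elitism in a noise-free world the per-generation best fitness is
nondecreasing.

**Enhancement bookkeeping.** The measured enhancement divides the best
mask's *noise-free* fitness by the mean noise-free fitness of 100 fresh
Bernoulli(½) masks on the same matrix. On a single matrix realization
this conditional baseline fluctuates around the ensemble value (strongly
so for small N·M), so measured enhancements can exceed the ensemble
theory; at the default N = 576 / M = 7 scale the noise-free GA lands
within a few percent of `η_exact = 13.14`.

## What the simulation does and does not show

The generator reproduces the study conditions: fully developed speckle,
a 6.6 MHz band-limited pulse, white noise at unprocessed SNR 3.86,
in-band clutter with the reported correlation statistics, and the
50×80×5 acquisition budget. Passing tests therefore show that the
extraction chain and optimizer behave as reported *under those
assumptions*. They do not show robustness to what the model omits:
speckle decorrelation during the run (the medium is static here),
laser-energy drift, transducer impulse-response detail beyond a smooth
passband, acoustic attenuation and diffraction, nonlinear photoacoustic
response, or the real (uncharacterized) clutter amplitude distribution.
The two-point experiment's unequal published enhancements stem from a
transducer sensitivity profile that is not printed; the per-absorber
`sensitivity` field exists for studying that effect, but no numeric
reproduction is attempted.

## Numerical choices

- All randomness flows through `numpy` `SeedSequence` folding of named
  integer seeds; every derived seed stays below 2³².
- The unit pulse is cached per (frequency, arrival, passband, grid);
  acquisition cost is dominated by the wavelet transform and the FFTs
  of clutter synthesis (~1 ms/shot), keeping a full 80×50×5 closed loop
  around half a minute on one CPU.
- Trace files store 12-significant-digit ASCII; round trips are lossless
  to 1e-12.
- Parseval/energy invariants are exact for the periodized (orthogonal)
  DWT and are tested there; the pipeline default is symmetric extension,
  which trades exact orthogonality at the boundary for smaller edge
  artifacts on gated records.
- Non-power-of-two record lengths are allowed; the decomposition depth
  caps at `pywt.dwt_max_level` with a logged warning.
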