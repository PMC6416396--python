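"""Forward model: speckle statistics, pulse synthesis, noise and clutter."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from pafocus.forward_sim import (
    AbsorberSpec,
    GeometryError,
    Mask,
    NoiseSpec,
    Trace,
    acquire,
    add_clutter,
    add_noise,
    clutter_burst,
    make_default_world,
    pa_amplitude,
    sample_transmission_matrix,
    speckle_intensities,
    synthesize_waveform,
)


class TestTransmissionMatrix:
    def test_seeded_determinism(self):
        a = sample_transmission_matrix(1, 1, seed=7)
        b = sample_transmission_matrix(1, 1, seed=7)
        assert np.array_equal(a.entries, b.entries)

    def test_shape_contract(self):
        tm = sample_transmission_matrix(3, 5, seed=0)
        assert tm.entries.shape == (3, 5)
        assert tm.m_modes == 3 and tm.n_segments == 5

    def test_circular_gaussian_mean(self):
        # 500 draws: each component's sample mean within 3 standard errors
        tm = sample_transmission_matrix(500, 1, seed=11)
        se = 3.0 / np.sqrt(2 * 500)  # component std is 1/sqrt(2)
        mean = tm.entries.mean()
        assert abs(mean.real) < se and abs(mean.imag) < se

    def test_invalid_dimensions(self):
        with pytest.raises(GeometryError):
            sample_transmission_matrix(0, 5, seed=0)
        with pytest.raises(GeometryError):
            sample_transmission_matrix(5, -1, seed=0)

    def test_intensity_exponential_law(self):
        """Per-mode intensity under a fixed mask is Exp(k) across realizations."""
        rng = np.random.default_rng(5)
        k = 7
        mask = Mask(np.array([1] * k + [0] * 13, dtype=np.uint8))
        tm = sample_transmission_matrix(10_000, 20, seed=21)
        intensities = speckle_intensities(tm, mask)
        _, p = stats.kstest(intensities / k, "expon")
        assert p > 0.01

    def test_all_on_vs_random_mean_ratio(self):
        """All-on expected intensity is twice the Bernoulli(1/2) mask mean."""
        n = 24
        tm = sample_transmission_matrix(10_000, n, seed=3)
        rng = np.random.default_rng(17)
        all_on = speckle_intensities(tm, Mask.all_on(n)).mean()
        random_mean = np.mean(
            [
                speckle_intensities(tm, Mask.random(n, rng)).mean()
                for _ in range(200)
            ]
        )
        assert all_on / random_mean == pytest.approx(2.0, rel=0.1)


class TestSpeckleIntensities:
    def test_all_zero_mask(self):
        tm = sample_transmission_matrix(4, 6, seed=0)
        assert np.all(speckle_intensities(tm, Mask.all_off(6)) == 0.0)

    def test_single_open_segment(self):
        tm = sample_transmission_matrix(4, 6, seed=0)
        bits = np.zeros(6, dtype=np.uint8)
        bits[2] = 1
        got = speckle_intensities(tm, Mask(bits))
        assert got == pytest.approx(np.abs(tm.entries[:, 2]) ** 2)

    def test_constructive_sum_of_identical_entries(self):
        t = 0.3 - 0.4j
        tm = sample_transmission_matrix(1, 2, seed=0)
        tm = dataclasses.replace(tm, entries=np.array([[t, t]]))
        got = speckle_intensities(tm, Mask(np.array([1, 1], dtype=np.uint8)))
        assert got[0] == pytest.approx(4 * abs(t) ** 2)

    def test_length_mismatch(self):
        tm = sample_transmission_matrix(2, 4, seed=0)
        with pytest.raises(GeometryError):
            speckle_intensities(tm, Mask.all_on(5))


class TestPaAmplitude:
    def test_direct_products(self, absorber):
        unit = dataclasses.replace(absorber, grueneisen=1.0, mu_a=1.0)
        assert pa_amplitude(np.array([2.0]), unit) == pytest.approx(2.0)
        scaled = dataclasses.replace(absorber, grueneisen=0.2, mu_a=0.5)
        assert pa_amplitude(np.array([4.0, 6.0]), scaled) == pytest.approx(1.0)

    def test_linearity_in_mu_a(self, absorber):
        doubled = dataclasses.replace(absorber, mu_a=2 * absorber.mu_a)
        i = np.array([1.0, 2.5])
        assert pa_amplitude(i, doubled) == pytest.approx(2 * pa_amplitude(i, absorber))

    def test_sensitivity_scaling(self, absorber):
        i = np.array([3.0])
        assert pa_amplitude(i, absorber, sensitivity=2.0) == pytest.approx(
            2 * pa_amplitude(i, absorber)
        )


class TestSynthesizeWaveform:
    def test_spectral_peak_at_characteristic_frequency(self, clean_pulse):
        """150 um absorber in water: spectrum peaks within 10% of 6.6 MHz."""
        spec = np.abs(np.fft.rfft(clean_pulse.samples))
        freqs = np.fft.rfftfreq(len(clean_pulse), clean_pulse.dt)
        peak = freqs[spec.argmax()]
        assert peak == pytest.approx(6.6e6, rel=0.10)

    def test_zero_amplitude_gives_zero_trace(self, absorber, transducer):
        tr = synthesize_waveform(0.0, absorber, transducer, 1500.0, 5e-9, 1024)
        assert np.all(tr.samples == 0.0)

    def test_peak_to_peak_linearity(self, absorber, transducer):
        a = synthesize_waveform(1.0, absorber, transducer, 1500.0, 5e-9, 2048)
        b = synthesize_waveform(2.0, absorber, transducer, 1500.0, 5e-9, 2048)
        ra = a.samples.max() - a.samples.min()
        rb = b.samples.max() - b.samples.min()
        assert rb / ra == pytest.approx(2.0, abs=1e-9)

    def test_bipolar_zero_mean(self, clean_pulse):
        assert clean_pulse.samples.max() > 0 and clean_pulse.samples.min() < 0
        assert abs(clean_pulse.samples.mean()) < 1e-6 * np.abs(clean_pulse.samples).max()

    def test_undersampling_rejected(self, absorber, transducer):
        with pytest.raises(GeometryError):
            synthesize_waveform(1.0, absorber, transducer, 1500.0, 1e-7, 1024)


class TestNoise:
    def test_sigma_zero_identity(self):
        tr = Trace(np.arange(8, dtype=float), dt=1e-8)
        assert add_noise(tr, NoiseSpec(sigma=0.0)) is tr

    def test_noise_std(self):
        tr = Trace(np.zeros(10_000), dt=1e-8)
        out = add_noise(tr, NoiseSpec(sigma=1.0, seed=42))
        assert 0.97 <= out.samples.std() <= 1.03

    def test_seeded_repeatability(self):
        tr = Trace(np.zeros(64), dt=1e-8)
        spec = NoiseSpec(sigma=0.5, seed=9)
        assert np.array_equal(add_noise(tr, spec).samples, add_noise(tr, spec).samples)


class TestClutter:
    def test_rate_zero_identity(self):
        tr = Trace(np.zeros(128), dt=1e-8)
        assert add_clutter(tr, NoiseSpec(sigma=0.0, clutter_rate=0.0)) is tr

    def test_positions_differ_across_seeds(self):
        tr = Trace(np.zeros(4096), dt=4e-9)
        outs = []
        for seed in (1, 2):
            spec = NoiseSpec(sigma=0.0, clutter_rate=3.0, clutter_amp=1.0, seed=seed)
            outs.append(add_clutter(tr, spec).samples)
        centers = [np.abs(o).argmax() for o in outs]
        assert centers[0] != centers[1]

    def test_burst_spectrum_peaks_in_transducer_passband(self):
        """Ensemble burst spectrum peaks inside the 3-7 MHz passband."""
        spec = NoiseSpec(sigma=0.0, clutter_rate=1.0, clutter_amp=1.0)
        acc = np.zeros(2049)
        for i in range(30):
            b = clutter_burst(4096, 4e-9, 8e-6, spec, np.random.default_rng(i))
            acc += np.abs(np.fft.rfft(b))
        freqs = np.fft.rfftfreq(4096, 4e-9)
        peak = freqs[acc.argmax()]
        assert 3e6 <= peak <= 7e6


class TestAcquire:
    def test_noise_free_composition_identity(self, small_quiet_world):
        world = small_quiet_world
        mask = Mask.all_on(world.n_segments)
        got = acquire(mask, world, seed=0)
        intensities = speckle_intensities(world.tm, mask)
        amp = pa_amplitude(intensities, world.absorbers[0], world.sensitivity(0))
        expected = synthesize_waveform(
            amp, world.absorbers[0], world.transducer, world.c_s, world.dt, world.n_samples
        )
        assert got.samples == pytest.approx(expected.samples)

    def test_all_zero_mask_silent(self, small_quiet_world):
        got = acquire(Mask.all_off(small_quiet_world.n_segments), small_quiet_world, 0)
        assert np.all(got.samples == 0.0)

    def test_two_absorbers_separated_by_travel_time(self):
        """Two absorbers 500 um apart arrive 500 um / c_s apart in time."""
        world = make_default_world(
            seed=2, n_segments=32, m_modes=2, sigma=0.0, clutter_rate=0.0, two_point=True
        )
        tr = acquire(Mask.all_on(32), world, 0)
        t1, t2 = (a.arrival_time for a in world.absorbers)
        assert t2 - t1 == pytest.approx(500e-6 / world.c_s)
        # each pulse peaks near its own arrival time
        mid = int(((t1 + t2) / 2) / world.dt)
        p1 = np.abs(tr.samples[:mid]).argmax() * world.dt
        p2 = (mid + np.abs(tr.samples[mid:]).argmax()) * world.dt
        period = 1.0 / 6.6e6
        assert abs(p1 - t1) < period and abs(p2 - t2) < period

    def test_deterministic_given_seed(self, default_world):
        mask = Mask.random(default_world.n_segments, np.random.default_rng(0))
        a = acquire(mask, default_world, 5)
        b = acquire(mask, default_world, 5)
        assert np.array_equal(a.samples, b.samples)

    def test_clutter_seed_changes_only_clutter(self, default_world):
        """Re-seeding the clutter stream leaves the white noise untouched."""
        world = default_world
        mask = Mask.random(world.n_segments, np.random.default_rng(1))
        base = acquire(mask, world, 3)
        reclutter = dataclasses.replace(
            world,
            noise=dataclasses.replace(world.noise, clutter_seed=world.noise.seed + 99),
        )
        other = acquire(mask, reclutter, 3)
        assert not np.array_equal(base.samples, other.samples)
        # with clutter disabled, the clutter seed is irrelevant: the white
        # noise stream is untouched
        quiet = dataclasses.replace(
            world, noise=dataclasses.replace(world.noise, clutter_rate=0.0)
        )
        quiet_reseeded = dataclasses.replace(
            quiet,
            noise=dataclasses.replace(quiet.noise, clutter_seed=world.noise.seed + 99),
        )
        assert np.array_equal(
            acquire(mask, quiet, 3).samples, acquire(mask, quiet_reseeded, 3).samples
        )
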