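"""Phase-locked/noise spike trains, the alpha synapse, and binaural combination."""

import numpy as np
import pytest
from scipy import integrate, stats

from laminaris import (
    ConductanceTrace,
    InputParams,
    SpikeTrain,
    alpha_kernel,
    binaural_conductance,
    conductance_from_trains,
    generate_phase_locked_train,
    generate_poisson_train,
    kappa_from_vs,
    vector_strength,
    vs_from_kappa,
)


class TestVonMisesConcentration:
    def test_zero_vector_strength_is_homogeneous(self):
        assert kappa_from_vs(0.0) == 0.0

    def test_default_concentration_against_quadrature(self):
        """kappa(0.6) checked against direct integration of the phase density."""
        kappa = kappa_from_vs(0.6)
        num, _ = integrate.quad(
            lambda th: np.cos(th) * np.exp(kappa * np.cos(th)), -np.pi, np.pi
        )
        den, _ = integrate.quad(lambda th: np.exp(kappa * np.cos(th)), -np.pi, np.pi)
        assert num / den == pytest.approx(0.6, abs=1e-8)
        assert kappa == pytest.approx(1.5157, abs=1e-3)

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.6, 0.9, 0.99])
    def test_round_trip(self, r):
        assert vs_from_kappa(kappa_from_vs(r)) == pytest.approx(r, abs=1e-8)

    def test_rejects_perfect_locking(self):
        with pytest.raises(ValueError):
            kappa_from_vs(1.0)


class TestAlphaKernel:
    def test_causal_and_peaked(self):
        assert alpha_kernel(-0.01, 1.3, 0.0409) == 0.0
        assert alpha_kernel(0.0409, 1.3, 0.0409) == pytest.approx(1.3, rel=1e-12)

    def test_half_amplitude_width(self):
        tau = 0.0409
        t = np.linspace(0, 10 * tau, 200001)
        g = alpha_kernel(t, 1.0, tau)
        above = t[g >= 0.5]
        width = above[-1] - above[0]
        assert width == pytest.approx(2.446 * tau, rel=1e-3)


class TestTrainGeneration:
    def test_zero_rate_empty(self):
        rng = np.random.default_rng(0)
        assert len(generate_poisson_train(0.0, 1000.0, rng)) == 0

    def test_poisson_mean_rate_and_isi_distribution(self):
        rng = np.random.default_rng(1)
        n_fib, dur = 200, 1000.0
        trains = [generate_poisson_train(500.0, dur, rng) for _ in range(n_fib)]
        counts = np.array([len(t) for t in trains])
        expect = 500.0
        se = np.sqrt(expect / n_fib)
        assert counts.mean() == pytest.approx(expect, abs=2 * se)
        isi = np.concatenate([np.diff(t.times) for t in trains])
        # exponentiality of inter-event intervals
        _, pval = stats.kstest(isi, "expon", args=(0, isi.mean()))
        assert pval > 0.01

    def test_phase_locked_mean_rate(self):
        p = InputParams()
        dur, n_fib = 1000.0, 100
        counts = [
            len(generate_phase_locked_train(p, dur, np.random.default_rng([2, j])))
            for j in range(n_fib)
        ]
        se = np.sqrt(500.0 / n_fib)
        assert np.mean(counts) == pytest.approx(500.0, abs=2 * se)

    def test_phase_locked_vector_strength_and_histogram(self):
        """Pooled spikes recover r = 0.6 and the von Mises phase profile."""
        p = InputParams()
        times = np.concatenate(
            [
                generate_phase_locked_train(p, 1500.0, np.random.default_rng([3, j])).times
                for j in range(150)
            ]
        )
        n = len(times)
        assert n > 1e5
        r_hat = vector_strength(times, p.f_stim)
        assert r_hat == pytest.approx(0.6, abs=2.0 / np.sqrt(n))
        # chi-square goodness of fit of the phase histogram
        phase = np.mod(times * p.f_stim * 1e-3, 1.0)
        nbins = 36
        observed, edges = np.histogram(phase, bins=nbins, range=(0, 1))
        kappa = p.kappa
        probs = []
        for k in range(nbins):
            num, _ = integrate.quad(
                lambda x: np.exp(kappa * np.cos(2 * np.pi * x)), edges[k], edges[k + 1]
            )
            probs.append(num)
        probs = np.array(probs) / np.sum(probs)
        _, pval = stats.chisquare(observed, n * probs)
        assert pval > 0.01

    def test_zero_vs_reduces_to_homogeneous(self):
        p = InputParams(r=0.0)
        tr = generate_phase_locked_train(p, 2000.0, np.random.default_rng(4))
        r_hat = vector_strength(tr.times, p.f_stim)
        assert r_hat < 2.5 / np.sqrt(len(tr))  # Rayleigh null scale

    def test_train_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([2.0, 1.0]), duration=10.0)
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([1.0, 11.0]), duration=10.0)


class TestConductance:
    def test_empty_trains_give_zero_trace(self):
        p = InputParams()
        g = conductance_from_trains([], p, 0.01, duration=10.0)
        assert np.all(g.values == 0.0)
        assert len(g.values) == 1001

    def test_single_spike_equals_kernel(self):
        p = InputParams()
        t0 = 1.0
        tr = SpikeTrain(times=np.array([t0]), duration=5.0)
        g = conductance_from_trains(tr, p, 0.01)
        expected = alpha_kernel(g.times - t0, p.h_alpha, p.tau_alpha)
        inside = g.times <= t0 + 10 * p.tau_alpha
        np.testing.assert_allclose(g.values[inside], expected[inside], rtol=1e-12)

    def test_linearity_of_superposition(self):
        p = InputParams()
        rng = np.random.default_rng(5)
        a = [generate_poisson_train(500.0, 50.0, rng) for _ in range(5)]
        b = [generate_poisson_train(500.0, 50.0, rng) for _ in range(7)]
        g_a = conductance_from_trains(a, p, 0.01)
        g_b = conductance_from_trains(b, p, 0.01)
        g_ab = conductance_from_trains(a + b, p, 0.01)
        np.testing.assert_allclose(g_ab.values, g_a.values + g_b.values, rtol=1e-9,
                                   atol=1e-12)

    def test_mean_conductance_matches_kernel_area(self):
        """Long-run mean = rate * integral(alpha); the integral via quadrature."""
        p = InputParams()
        rng = np.random.default_rng(6)
        n_fib, dur = 300, 2000.0
        trains = [generate_poisson_train(500.0, dur, rng) for _ in range(n_fib)]
        g = conductance_from_trains(trains, p, 0.01)
        t = np.linspace(0, 12 * p.tau_alpha, 20001)
        area = np.trapezoid(alpha_kernel(t, p.h_alpha, p.tau_alpha), t)
        rate_per_ms = n_fib * 500.0 * 1e-3
        expected = rate_per_ms * area  # ~21.7 nS for 300 fibers at 500 Hz
        n_events = sum(len(tr) for tr in trains)
        se = expected / np.sqrt(n_events)
        assert expected == pytest.approx(21.7, abs=0.1)
        assert g.values.mean() == pytest.approx(expected, abs=2 * se)

    def test_non_negativity(self):
        p = InputParams()
        rng = np.random.default_rng(7)
        trains = [generate_phase_locked_train(p, 100.0, rng) for _ in range(20)]
        g = conductance_from_trains(trains, p, 0.01)
        assert np.all(g.values >= 0.0)


@pytest.fixture(scope="module")
def pair():
    p = InputParams(m=60)
    rng_i = np.random.default_rng(8)
    rng_c = np.random.default_rng(9)
    ipsi = [generate_phase_locked_train(p, 250.0, rng_i) for _ in range(p.m)]
    contra = [generate_phase_locked_train(p, 250.0, rng_c) for _ in range(p.m)]
    g_i = conductance_from_trains(ipsi, p, 0.01)
    g_c = conductance_from_trains(contra, p, 0.01)
    return p, g_i, g_c


class TestBinauralCombination:

    def test_zero_delta_is_plain_sum(self, pair):
        p, g_i, g_c = pair
        g = binaural_conductance(g_i, g_c, 0.0, p.f_stim)
        np.testing.assert_array_equal(g.values, g_i.values + g_c.values)

    def test_full_cycle_equals_zero_shift(self, pair):
        # 2*pi at 4 kHz = 0.25 ms = an exact number of grid steps
        p, g_i, g_c = pair
        g2pi = binaural_conductance(g_i, g_c, 2.0 * np.pi, p.f_stim)
        shifted = g_i.values + np.roll(g_c.values, -25)
        np.testing.assert_array_equal(g2pi.values, shifted)

    def test_antiphase_cancels_stimulus_component(self, pair):
        """delta = pi minimizes the 4-kHz Fourier component of the drive."""
        p, g_i, g_c = pair

        def component(delta):
            g = binaural_conductance(g_i, g_c, delta, p.f_stim).values
            ph = np.exp(-2j * np.pi * p.f_stim * 1e-3 * np.arange(len(g)) * 0.01)
            return np.abs((g * ph).mean())

        c0, cpi = component(0.0), component(np.pi)
        assert cpi < 0.2 * c0

    def test_grid_mismatch_rejected(self, pair):
        p, g_i, _ = pair
        other = ConductanceTrace(dt=0.02, values=np.zeros(100))
        with pytest.raises(ValueError):
            binaural_conductance(g_i, other, 0.0, p.f_stim)
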