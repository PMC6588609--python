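"""Dephasing spectra, Parseval consistency, b-tensors and the attenuation
integral."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdetune import (
    GAMMA_PROTON,
    adc,
    attenuation,
    b_tensor,
    band_power,
    dephasing_spectrum,
    dephasing_time,
    make_model,
)
from mdetune.waveform import Waveform

from conftest import D0, make_pgse


def random_refocused_waveform(rng, n=200, dt=1e-4):
    g = rng.normal(size=(n, 3)) * 1e-3
    g -= g.mean(axis=0)
    return Waveform(g, dt)


class TestDephasing:
    def test_pgse_plateau_at_gamma_g_delta(self):
        g, delta = 0.1, 5e-3
        w = make_pgse(g=g, delta=delta, Delta=15e-3)
        F = dephasing_time(w).values
        plateau = GAMMA_PROTON * g * delta
        i_mid = w.n_samples // 2
        assert F[i_mid, 0] == pytest.approx(plateau, rel=1e-12)

    def test_zero_waveform_zero_trace(self):
        w = Waveform(np.zeros((50, 3)), 1e-5)
        assert np.all(dephasing_time(w).values == 0.0)

    def test_fixture_starts_and_ends_at_zero(self, iso_wave):
        F = dephasing_time(iso_wave).values
        mag = np.linalg.norm(F, axis=1)
        assert mag[0] == 0.0
        assert mag[-1] <= 1e-9 * mag.max()


class TestParseval:
    def test_trace_b_time_vs_frequency(self, all_waves, all_spectra):
        for lab, w in all_waves.items():
            b_time = b_tensor(w).b
            b_freq = all_spectra[lab].b_value()
            assert b_freq == pytest.approx(b_time, rel=1e-4), lab

    def test_full_tensor_time_vs_frequency(self, iso_wave, all_spectra):
        Mt = b_tensor(iso_wave).matrix
        Mf = all_spectra["isotropic"].b_tensor().matrix
        np.testing.assert_allclose(Mf, Mt, rtol=1e-4, atol=1e-4 * Mt.trace())

    def test_time_shift_leaves_power_spectrum(self):
        w = make_pgse(dt=1e-5)
        pad = np.zeros((200, 3))
        shifted = Waveform(np.vstack([pad, w.g]), w.dt)
        s0 = dephasing_spectrum(w, zero_pad_to=2 ** 18)
        s1 = dephasing_spectrum(shifted, zero_pad_to=2 ** 18)
        np.testing.assert_allclose(s1.power, s0.power, rtol=1e-7,
                                   atol=1e-10 * s0.power.max())


class TestBTensor:
    def test_single_axis_waveform_is_rank_one(self, tuned_wave):
        ev = b_tensor(tuned_wave).eigenvalues
        assert ev[0] == pytest.approx(0.0, abs=1e-12 * ev[-1])
        assert ev[1] == pytest.approx(0.0, abs=1e-12 * ev[-1])

    def test_fixture_is_isotropic(self, iso_wave):
        assert b_tensor(iso_wave).eigenvalue_spread <= 0.05

    def test_positive_semidefinite(self, rng):
        for _ in range(5):
            w = random_refocused_waveform(rng)
            ev = b_tensor(w).eigenvalues
            assert ev.min() >= -1e-10 * max(ev.max(), 1.0)


class TestAttenuation:
    def test_flat_spectrum_beta_is_b_times_d0(self, rng):
        free = make_model("free", D0=D0)
        for _ in range(20):
            w = random_refocused_waveform(rng, n=150)
            spec = dephasing_spectrum(w, zero_pad_to=2 ** 16)
            beta = attenuation(spec, free)
            assert beta == pytest.approx(spec.b_value() * D0, rel=1e-6)

    def test_isotropic_encoding_sees_only_mean_diffusivity(self, all_spectra, rng):
        from scipy.spatial.transform import Rotation

        spec = all_spectra["isotropic"]
        eigs = (1.5e-9, 0.4e-9, 0.1e-9)
        base = attenuation(spec, make_model(eigenvalues=eigs))
        expected = spec.b_value() * np.mean(eigs)
        assert base == pytest.approx(expected, rel=0.05)
        for R in Rotation.random(5, random_state=np.random.RandomState(1)).as_matrix():
            rotated = attenuation(spec, make_model(eigenvalues=eigs, rotation=R))
            assert rotated == pytest.approx(base, rel=0.05)

    def test_beta_additive_over_mixture_spectra(self, all_spectra):
        # linearity of the attenuation integral in D(omega)
        spec = all_spectra["tuned"]
        m1 = make_model("sphere", R=2.5e-6, D0=D0)
        m2 = make_model("free", D0=D0)
        b1, b2 = attenuation(spec, m1), attenuation(spec, m2)

        # direct check of quadrature linearity: weighted sum of spectra
        class Mix:
            rotation = np.eye(3)

            def axis_spectra(self, omega):
                return 0.25 * m1.axis_spectra(omega) + 0.75 * m2.axis_spectra(omega)

        assert attenuation(spec, Mix()) == pytest.approx(0.25 * b1 + 0.75 * b2,
                                                         rel=1e-10)

    def test_free_diffusion_adc_is_d0(self, all_spectra):
        free = make_model("free", D0=D0)
        for lab, spec in all_spectra.items():
            assert adc(spec, free) == pytest.approx(D0, rel=1e-9), lab

    def test_long_time_limit_restricted_adc_vanishes(self, iso_wave):
        # stretch the encoding so the restriction is probed far beyond its
        # correlation time: ADC -> 0
        spec = dephasing_spectrum(iso_wave.time_stretched(20.0))
        sphere = make_model("sphere", R=1e-6, D0=D0)
        assert adc(spec, sphere) < 5e-3 * D0

    def test_adc_errors_on_zero_b(self):
        w = Waveform(np.zeros((64, 3)), 1e-5)
        spec = dephasing_spectrum(w, zero_pad_to=2 ** 14)
        with pytest.raises(ValueError):
            adc(spec, make_model("free", D0=D0))


class TestBandPower:
    def test_full_band_returns_b(self, all_spectra):
        for lab, spec in all_spectra.items():
            nyq = spec.omega[-1] / (2 * np.pi)
            assert band_power(spec, nyq) == pytest.approx(spec.b_value(), rel=1e-12)

    def test_zero_cut_keeps_only_the_dc_bin(self, all_spectra):
        # the band integral vanishes with the bandwidth; on the discrete grid
        # a zero cut retains just the DC bin, a tiny fraction of b
        spec = all_spectra["tuned"]
        dc = np.abs(spec.values[0]) ** 2
        expected = dc.sum() * spec.domega / (2.0 * np.pi)
        assert band_power(spec, 0.0) == pytest.approx(expected, rel=1e-12)
        assert band_power(spec, 0.0) <= 0.01 * spec.b_value()

    def test_partition_sums_to_b(self, all_spectra):
        spec = all_spectra["isotropic"]
        cuts = [0.0, 50.0, 200.0, 1000.0, spec.omega[-1] / (2 * np.pi)]
        total = sum(band_power(spec, hi) - band_power(spec, lo)
                    for lo, hi in zip(cuts[:-1], cuts[1:]))
        assert total + band_power(spec, 0.0) == pytest.approx(spec.b_value(),
                                                              rel=1e-6)

    def test_detuned_has_more_low_frequency_power(self, all_spectra):
        b = all_spectra["tuned"].b_value()
        p_tuned = band_power(all_spectra["tuned"], 50.0) / b
        p_detuned = band_power(all_spectra["detuned"], 50.0) / b
        assert p_detuned > p_tuned

    def test_per_axis_powers_sum_to_trace(self, all_spectra):
        spec = all_spectra["isotropic"]
        per_axis = sum(band_power(spec, 500.0, axis=i) for i in range(3))
        assert per_axis == pytest.approx(band_power(spec, 500.0), rel=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_parseval_random_waveforms(seed):
    """Parseval's identity holds for arbitrary refocused waveforms."""
    rng = np.random.default_rng(seed)
    w = random_refocused_waveform(rng, n=120, dt=2e-4)
    spec = dephasing_spectrum(w, zero_pad_to=2 ** 16, dt_spec=1e-5)
    assert spec.b_value() == pytest.approx(b_tensor(w).b, rel=1e-4)
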