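"""Shared fixtures: the frozen isotropic fixture waveform, its tuned and
detuned derivations, and their dephasing spectra (expensive, session-scoped)."""

import numpy as np
import pytest

from mdetune import (
    dephasing_spectrum,
    derive_detuned,
    derive_tuned,
    fixture_qmas,
)

D0 = 1e-9      # intrinsic diffusivity used throughout (m^2/s)
TAU = 23e-3    # encoding time of the fixture (s)


@pytest.fixture(scope="session")
def iso_wave():
    return fixture_qmas()


@pytest.fixture(scope="session")
def tuned_wave(iso_wave):
    return derive_tuned(iso_wave)


@pytest.fixture(scope="session")
def detuned_wave(iso_wave):
    return derive_detuned(iso_wave)


@pytest.fixture(scope="session")
def all_waves(iso_wave, tuned_wave, detuned_wave):
    return {"isotropic": iso_wave, "tuned": tuned_wave, "detuned": detuned_wave}


@pytest.fixture(scope="session")
def all_spectra(all_waves):
    return {k: dephasing_spectrum(w) for k, w in all_waves.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20230423)


def make_pgse(g=0.1, delta=5e-3, Delta=15e-3, dt=1e-5):
    """Ideal single-axis pulsed-gradient pair: +g for delta, gap, -g for delta."""
    from mdetune.waveform import Waveform

    n_delta = int(round(delta / dt))
    n_gap = int(round((Delta - delta) / dt))
    gx = np.concatenate([np.full(n_delta, g), np.zeros(n_gap), np.full(n_delta, -g)])
    arr = np.zeros((len(gx), 3))
    arr[:, 0] = gx
    return Waveform(arr, dt, label="custom")
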