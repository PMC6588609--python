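"""Synthetic multi-compartment systems and protocol emulation.

The phantom archetypes emulate the four reference samples of the
tuned/detuned encoding experiment —

* ``yeast``          large isotropic restrictions: 50% impermeable spheres
                     (R = 2.5 um) + 50% free diffusion;
* ``microfibers``    large anisotropic restrictions: liquid-filled hollow
                     fibers (R = 5 um) plus micron-scale interstitial
                     channels between packed fibers, uniformly dispersed;
* ``liquid_crystal`` small anisotropic restrictions: ~4 nm-diameter aqueous
                     channels, modelled as impermeable R = 2 nm cylinders,
                     uniformly dispersed;
* ``polymer``        free multi-Gaussian diffusion (aqueous polymer
                     solution);

— plus three illustrative brain-ROI archetypes (``wm``, ``gm``,
``cerebellum``) and a ``pbs`` control.  Tissue fractions are documented
defaults, not fits to any measured curve.

Signals are predicted per compartment in the Gaussian (mono-exponential per
compartment) approximation: the frequency-domain ADC of each compartment at
each encoding orientation fixes E(o, b) = sum_c f_c exp(-ADC_co b), which is
then powder averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import b_from_scanner
from .restricted import DiffusionModel, make_model
from .powder import OrientationSet, SignalCurve, orientation_set
from .spectral import attenuation_multi, dephasing_spectrum
from .waveform import Waveform, derive_detuned, derive_tuned, fixture_qmas

__all__ = [
    "CompartmentSystem",
    "Protocol",
    "make_phantom",
    "predict_signals",
    "system_adcs",
    "add_rician_noise",
    "render_volume",
    "PHANTOM_KINDS",
]

#: default intrinsic diffusivity, m^2/s
D0_DEFAULT = 1e-9

PHANTOM_KINDS = ("yeast", "microfibers", "liquid_crystal", "polymer",
                 "wm", "gm", "cerebellum", "pbs")


@dataclass(frozen=True)
class CompartmentSystem:
    """Weighted mixture of diffusion models; fractions sum to one."""

    components: tuple[tuple[DiffusionModel, float], ...]
    name: str = "system"

    def __post_init__(self):
        comps = tuple((m, float(f)) for m, f in self.components)
        fracs = np.array([f for _, f in comps])
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ValueError("signal fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-10:
            raise ValueError(f"signal fractions must sum to 1, got {fracs.sum()}")
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class Protocol:
    """Acquisition emulation: three encodings, b grid, orientations.

    Defaults follow the reference protocol: encoding time tau = 23 ms,
    12 b-values logarithmically spaced between 240 and 4800 s/mm^2,
    15 uniformly distributed orientations.  All waveforms must share tau,
    and their b-values (before per-step amplitude scaling) must agree to 1%.
    """

    waveforms: dict[str, Waveform]
    b_values: np.ndarray = field(default_factory=lambda: default_b_grid())
    n_orientations: int = 15
    orientation_scheme: str = "fibonacci"

    def __post_init__(self):
        from .spectral import b_tensor

        object.__setattr__(self, "b_values", np.asarray(self.b_values, dtype=float))
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        taus = [w.tau for w in self.waveforms.values()]
        if max(taus) - min(taus) > 1e-9 * max(taus):
            raise ValueError("all protocol waveforms must share the encoding time")
        bs = [b_tensor(w).b for w in self.waveforms.values()]
        if (max(bs) - min(bs)) / np.mean(bs) > 0.01:
            raise ValueError("protocol waveforms must share trace(b) to 1%")

    @property
    def tau(self) -> float:
        return next(iter(self.waveforms.values())).tau

    def orientations(self) -> OrientationSet:
        return orientation_set(self.n_orientations, self.orientation_scheme, seed=0)


def default_b_grid(b_min: float = 240.0, b_max: float = 4800.0, n: int = 12,
                   include_zero: bool = True) -> np.ndarray:
    """Log-spaced b grid in s/m^2 (inputs in s/mm^2), optionally with b = 0."""
    grid = b_from_scanner(np.logspace(np.log10(b_min), np.log10(b_max), n))
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def default_protocol(n_orientations: int = 15, b_values: np.ndarray | None = None) -> Protocol:
    """The shipped three-encoding protocol built from the fixture waveform."""
    iso = fixture_qmas()
    waveforms = {"isotropic": iso, "tuned": derive_tuned(iso),
                 "detuned": derive_detuned(iso)}
    if b_values is None:
        return Protocol(waveforms, n_orientations=n_orientations)
    return Protocol(waveforms, b_values=b_values, n_orientations=n_orientations)


# ---------------------------------------------------------------------------
# phantom archetypes
# ---------------------------------------------------------------------------

def make_phantom(kind: str, D0: float = D0_DEFAULT, **params) -> CompartmentSystem:
    """Build a named compartment system.

    ``params`` override the documented defaults per kind (e.g. ``R_sphere``,
    ``f_restricted`` for yeast).  Unknown kinds raise with the valid list.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; valid kinds: {PHANTOM_KINDS}")
    if kind == "yeast":
        R = params.pop("R_sphere", 2.5e-6)
        f = params.pop("f_restricted", 0.5)
        comps = [(make_model("sphere", R=R, D0=D0), f),
                 (make_model("free", D0=D0), 1.0 - f)]
    elif kind == "microfibers":
        # intra-fiber lumen + interstitial channels of a packed bundle + a
        # small unrestricted pool; see the methods note for the rationale
        R_fiber = params.pop("R_fiber", 5e-6)
        R_channel = params.pop("R_channel", 1e-6)
        f_fiber = params.pop("f_fiber", 0.5)
        f_channel = params.pop("f_channel", 0.4)
        comps = [(make_model("cylinder", R=R_fiber, D0=D0), f_fiber),
                 (make_model("cylinder", R=R_channel, D0=D0), f_channel),
                 (make_model("free", D0=D0), 1.0 - f_fiber - f_channel)]
    elif kind == "liquid_crystal":
        R = params.pop("R_channel", 2e-9)
        comps = [(make_model("cylinder", R=R, D0=D0), 1.0)]
    elif kind == "polymer":
        # multi-Gaussian isotropic pools (water plus polymers of different
        # lengths); diffusivities in m^2/s, fractions sum to 1
        pools = params.pop("pools", ((0.55, 1.2e-9), (0.30, 3.5e-10), (0.15, 8e-11)))
        comps = [(make_model("free", D0=d), f) for f, d in pools]
    elif kind == "pbs":
        comps = [(make_model("free", D0=params.pop("D0_pbs", 2.0e-9)), 1.0)]
    elif kind == "wm":
        comps = [(make_model("cylinder", R=params.pop("R_axon", 0.5e-6), D0=D0), 0.45),
                 (make_model(eigenvalues=(D0, 0.25 * D0, 0.25 * D0)), 0.35),
                 (make_model("sphere", R=params.pop("R_glia", 4e-6), D0=D0), 0.20)]
    elif kind == "gm":
        comps = [(make_model("cylinder", R=params.pop("R_dendrite", 0.4e-6), D0=D0), 0.35),
                 (make_model(eigenvalues=(0.9 * D0,) * 3), 0.50),
                 (make_model("sphere", R=params.pop("R_soma", 6e-6), D0=D0), 0.15)]
    else:  # cerebellum
        comps = [(make_model("sphere", R=params.pop("R_granule", 3e-6), D0=D0), 0.40),
                 (make_model("cylinder", R=params.pop("R_dendrite", 0.4e-6), D0=D0), 0.35),
                 (make_model(eigenvalues=(0.9 * D0,) * 3), 0.25)]
    if params:
        raise ValueError(f"unrecognised parameters for {kind!r}: {sorted(params)}")
    return CompartmentSystem(tuple(comps), name=kind)


# ---------------------------------------------------------------------------
# signal prediction
# ---------------------------------------------------------------------------

def system_adcs(system: CompartmentSystem, waveform: Waveform,
                frames: np.ndarray) -> np.ndarray:
    """Per-(component, orientation) ADC under one encoding waveform.

    Orientation frames rotate each compartment relative to the gradient
    frame.  Because compartment attenuation is mono-exponential in b in the
    Gaussian approximation, these ADCs determine the signal at every
    amplitude scaling of the waveform.
    """
    spec = dephasing_spectrum(waveform)
    b_ref = spec.b_value()
    out = np.empty((len(system.components), len(frames)))
    for ci, (model, _) in enumerate(system.components):
        out[ci] = attenuation_multi(spec, model, frames) / b_ref
    return out


def predict_signals(system: CompartmentSystem, protocol: Protocol,
                    powder: bool = True) -> dict[str, SignalCurve | list[SignalCurve]]:
    """Powder-averaged attenuation curves per encoding type.

    Returns {label: SignalCurve}; with ``powder=False`` the per-orientation
    curves are returned instead ({label: [SignalCurve, ...]}).
    """
    frames = protocol.orientations().rotations
    fracs = np.array([f for _, f in system.components])
    result: dict[str, SignalCurve | list[SignalCurve]] = {}
    for label, w in protocol.waveforms.items():
        adcs = system_adcs(system, w, frames)           # (C, O)
        # E per orientation, b: sum_c f_c exp(-ADC_co * b)
        E = np.einsum("c,cob->ob", fracs,
                      np.exp(-adcs[:, :, None] * protocol.b_values[None, None, :]))
        curves = [SignalCurve(protocol.b_values, E[o], label) for o in range(len(frames))]
        result[label] = powder_from(curves) if powder else curves
    return result


def powder_from(curves: list[SignalCurve]) -> SignalCurve:
    from .powder import powder_average

    avg = powder_average(curves)
    return SignalCurve(avg.b, avg.E, avg.label, n_orientations=len(curves),
                       provenance="analytic")


def add_rician_noise(values: np.ndarray | SignalCurve, snr: float,
                     seed: int = 0) -> np.ndarray | SignalCurve:
    """Rician-distributed magnitude of (E + N(0, s)) + i N(0, s), s = 1/snr.

    Models magnitude reconstruction of complex data whose noise-free signal
    is real; the floor at E = 0 is the Rayleigh mean s * sqrt(pi/2).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    if isinstance(values, SignalCurve):
        noisy = add_rician_noise(values.E, snr, seed)
        return SignalCurve(values.b, noisy, values.label,
                           n_orientations=values.n_orientations,
                           provenance="synthetic-noisy")
    sigma = 1.0 / snr
    arr = np.asarray(values, dtype=float)
    real = arr + rng.normal(0.0, sigma, arr.shape)
    imag = rng.normal(0.0, sigma, arr.shape)
    return np.hypot(real, imag)


# ---------------------------------------------------------------------------
# synthetic volumes
# ---------------------------------------------------------------------------

def render_volume(label_map: np.ndarray, systems: dict[int, CompartmentSystem],
                  protocol: Protocol, snr: float | None = None, seed: int = 0,
                  voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Synthetic 4D signal volume from a labelled voxel grid.

    Every voxel of region ``label`` holds that region's per-(encoding, b,
    orientation) signal; frame metadata goes to a sidecar table with columns
    ``frame, waveform, b, orientation, n_orientations`` (b in s/m^2).
    Label 0 is background (zero signal).  Optional Rician noise with the
    given SNR is applied voxel-wise, seeded.

    Returns (volume4d, sidecar DataFrame, voxel_size_mm).
    """
    label_map = np.asarray(label_map)
    if label_map.ndim != 3:
        raise ValueError("label_map must be a 3D integer array")
    labels = sorted(int(v) for v in np.unique(label_map) if v != 0)
    missing = [l for l in labels if l not in systems]
    if missing:
        raise ValueError(f"no compartment system given for labels {missing}")

    frames_meta = []
    per_label_signals = {}
    n_or = protocol.n_orientations
    for lab_i, lab in enumerate(labels):
        curves = predict_signals(systems[lab], protocol, powder=False)
        sig = []
        for wname, per_orient in curves.items():
            for o, c in enumerate(per_orient):
                for bi, b in enumerate(protocol.b_values):
                    if lab_i == 0:
                        frames_meta.append((wname, b, o, n_or))
                    sig.append(c.E[bi])
        per_label_signals[lab] = np.asarray(sig)

    n_frames = len(frames_meta)
    vol = np.zeros(label_map.shape + (n_frames,))
    for lab in labels:
        vol[label_map == lab] = per_label_signals[lab]
    if snr is not None:
        vol = add_rician_noise(vol, snr, seed=seed)
        vol[label_map == 0] = 0.0
    sidecar = pd.DataFrame(frames_meta, columns=["waveform", "b", "orientation",
                                                 "n_orientations"])
    sidecar.insert(0, "frame", np.arange(n_frames))
    return vol, sidecar, voxel_size_mm
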