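"""Random-walk Monte Carlo simulation of restricted diffusion.

The simulator is the package's independent cross-check of the frequency-
domain engine: Gaussian displacement steps with per-axis variance 2 D0 dt,
impermeable barriers enforced by rejection (a particle whose step endpoint
would leave the restriction stays in place for that step), phase accumulated
as phi = gamma * sum_t g(t) . r(t) dt, and signal E = <cos phi>.

Because the gradient amplitude only scales the phase linearly, one walk
yields the signal at every requested b-value and for every waveform and
orientation simultaneously; the trajectory is simulated once and phases for
all (waveform, orientation) pairs are accumulated in the same pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import b_from_scanner
from .spectral import b_tensor
from .waveform import Waveform

__all__ = ["Substrate", "WalkConfig", "McResult", "run_walk", "mc_signal", "mc_adc"]

#: default b-value pair for the low-b ADC estimate: 0 and 100 s/mm^2 in s/m^2
ADC_B_PAIR = (0.0, b_from_scanner(100.0))


@dataclass(frozen=True)
class Substrate:
    """Restriction geometry for the walk: free, sphere, or infinite cylinder.

    The cylinder axis is the local z axis; orientations are applied by
    rotating the gradient into the substrate frame.
    """

    geometry: str
    D0: float
    R: float = 0.0

    def __post_init__(self):
        if self.geometry not in ("free", "sphere", "cylinder_infinite"):
            raise ValueError(f"unknown substrate geometry {self.geometry!r}")
        if self.geometry != "free" and not (self.R > 0):
            raise ValueError("restricted substrate needs R > 0")
        if not (self.D0 > 0):
            raise ValueError("D0 must be positive")


@dataclass(frozen=True)
class WalkConfig:
    """Walk discretisation: defaults follow the reference configuration
    (5000 time steps; 1e5 particles, reduced to 1e4 for routine testing)."""

    tau: float
    n_steps: int = 5000
    n_particles: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 100:
            raise ValueError("need at least 100 time steps")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")

    @property
    def dt_mc(self) -> float:
        return self.tau / self.n_steps


@dataclass(frozen=True)
class McResult:
    """Signals and ADCs per orientation from a Monte Carlo run.

    ``E[w][o, j]`` is the attenuation for waveform label w, orientation o and
    b-value ``b_values[j]``; ``stderr`` the matching standard error of the
    mean; ``imag_residual`` the magnitude of <sin phi> (zero in expectation)
    as a sanity metric.
    """

    b_values: np.ndarray
    orientations: np.ndarray
    E: dict[str, np.ndarray]
    stderr: dict[str, np.ndarray]
    imag_residual: dict[str, np.ndarray]
    n_particles: int = 0
    labels: tuple[str, ...] = field(default_factory=tuple)


def _rms_step(substrate: Substrate, cfg: WalkConfig) -> float:
    return float(np.sqrt(6.0 * substrate.D0 * cfg.dt_mc))


def _inside(substrate: Substrate, r: np.ndarray) -> np.ndarray:
    if substrate.geometry == "sphere":
        return (r * r).sum(axis=1) <= substrate.R ** 2
    if substrate.geometry == "cylinder_infinite":
        return r[:, 0] ** 2 + r[:, 1] ** 2 <= substrate.R ** 2
    return np.ones(len(r), dtype=bool)


def _initial_positions(substrate: Substrate, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions inside the restriction by rejection from the box."""
    if substrate.geometry == "free":
        return np.zeros((n, 3))
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-substrate.R, substrate.R, size=(2 * (n - filled) + 16, 3))
        if substrate.geometry == "cylinder_infinite":
            cand[:, 2] = 0.0  # axial position is irrelevant for an infinite cylinder
        ok = cand[_inside(substrate, cand)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def run_walk(substrate: Substrate, cfg: WalkConfig):
    """Generate the walk, yielding (step index, positions) per time step.

    Steps are Gaussian with variance 2 D0 dt per axis; a step whose endpoint
    would cross the barrier is rejected and the particle stays in place.
    Raises if the RMS step exceeds R/2, where rejection bias near the wall
    would dominate the result.
    """
    if substrate.geometry != "free" and _rms_step(substrate, cfg) > substrate.R / 2.0:
        raise ValueError(
            f"RMS step {_rms_step(substrate, cfg):.2e} m exceeds R/2; "
            "increase n_steps or reduce dt"
        )
    rng = np.random.default_rng(cfg.seed)
    r = _initial_positions(substrate, cfg.n_particles, rng)
    sigma = np.sqrt(2.0 * substrate.D0 * cfg.dt_mc)
    yield 0, r
    for k in range(1, cfg.n_steps + 1):
        step = rng.normal(0.0, sigma, size=r.shape)
        trial = r + step
        if substrate.geometry != "free":
            ok = _inside(substrate, trial)
            r = np.where(ok[:, None], trial, r)
        else:
            r = trial
        yield k, r


def _resample_gradient(w: Waveform, n_steps: int, tau: float) -> np.ndarray:
    """Gradient per walk step from the piecewise-linear dephasing (T/m)."""
    if abs(w.tau - tau) > 1e-9 * tau:
        raise ValueError("waveform duration does not match walk duration")
    dt_mc = tau / n_steps
    t_nodes = np.arange(w.n_samples + 1) * w.dt
    t_new = np.arange(n_steps + 1) * dt_mc
    F_old = w.dephasing()
    F_new = np.column_stack([np.interp(t_new, t_nodes, F_old[:, i]) for i in range(3)])
    return np.diff(F_new, axis=0) / (w.gamma * dt_mc)


def mc_signal(substrate: Substrate, cfg: WalkConfig,
              waveforms: Waveform | dict[str, Waveform],
              orientations: np.ndarray | None = None,
              b_values=None) -> McResult:
    """Signal attenuation E(b) per orientation for one or more waveforms.

    Parameters
    ----------
    waveforms : Waveform or {label: Waveform}
        All must share the walk duration.  Each is used as the *shape*; the
        amplitude is rescaled to every entry of ``b_values``.
    orientations : ndarray (n, 3, 3), optional
        Rotations of the substrate symmetry axis relative to the gradient
        frame (identity if omitted).  Implemented by inverse-rotating the
        gradient into the substrate frame.
    b_values : sequence of b-values in s/m^2
        Defaults to (0, 1e8) — the low-b pair used for ADC extraction.
    """
    if isinstance(waveforms, Waveform):
        waveforms = {waveforms.label: waveforms}
    if orientations is None:
        orientations = np.eye(3)[None]
    orientations = np.asarray(orientations, dtype=float)
    b_values = np.asarray(ADC_B_PAIR if b_values is None else b_values, dtype=float)

    labels = tuple(waveforms)
    n_or = len(orientations)
    dt_mc = cfg.dt_mc
    gamma = next(iter(waveforms.values())).gamma

    # per-step gradients in the substrate frame, all (waveform, orientation)
    # pairs stacked: G[w*n_or + o] has shape (n_steps, 3)
    G = []
    b_ref = []
    for lab in labels:
        g = _resample_gradient(waveforms[lab], cfg.n_steps, cfg.tau)
        b_ref.append(b_tensor(waveforms[lab]).b)
        for R in orientations:
            G.append(g @ R)  # row vectors: g . (R r) = (g R) . r
    G = np.asarray(G)                      # (W*O, n_steps, 3)
    b_ref = np.asarray(b_ref)

    phase = np.zeros((len(G), cfg.n_particles))
    r_prev = None
    for k, r in run_walk(substrate, cfg):
        if k == 0:
            r_prev = r
            continue
        r_mid = 0.5 * (r_prev + r)
        # accumulate gamma * g_k . r_mid * dt for every (waveform, orientation)
        phase += (G[:, k - 1, :] @ r_mid.T) * (gamma * dt_mc)
        r_prev = r

    E = {}
    stderr = {}
    imag = {}
    for i, lab in enumerate(labels):
        ph = phase[i * n_or:(i + 1) * n_or]        # (O, P)
        scale = np.sqrt(b_values / b_ref[i])        # (B,)
        E[lab] = np.empty((n_or, len(b_values)))
        stderr[lab] = np.empty((n_or, len(b_values)))
        imag[lab] = np.empty((n_or, len(b_values)))
        for j, s in enumerate(scale):              # one b at a time: bounded memory
            phi = ph * s
            c = np.cos(phi)
            E[lab][:, j] = c.mean(axis=1)
            stderr[lab][:, j] = c.std(axis=1) / np.sqrt(cfg.n_particles)
            imag[lab][:, j] = np.abs(np.sin(phi).mean(axis=1))
    return McResult(b_values, orientations, E, stderr, imag,
                    n_particles=cfg.n_particles, labels=labels)


def mc_adc(result: McResult, label: str | None = None,
           b_pair: tuple[float, float] = ADC_B_PAIR) -> np.ndarray:
    """Per-orientation ADC from the exponential decay between two b-values.

    The default pair is (0, 100 s/mm^2): ADC = -ln(E(b2)/E(b1)) / (b2 - b1).
    """
    if label is None:
        if len(result.labels) != 1:
            raise ValueError("result holds several waveforms; pass a label")
        label = result.labels[0]
    b1, b2 = b_pair
    idx1 = _find_b(result.b_values, b1)
    idx2 = _find_b(result.b_values, b2)
    E = result.E[label]
    if np.any(E[:, idx2] <= 0) or np.any(E[:, idx1] <= 0):
        raise ValueError("non-positive signal at the ADC b-values; "
                         "increase the particle count")
    return -np.log(E[:, idx2] / E[:, idx1]) / (b2 - b1)


def _find_b(b_values: np.ndarray, b: float) -> int:
    i = int(np.argmin(np.abs(b_values - b)))
    if abs(b_values[i] - b) > 1e-6 * max(b, 1.0):
        raise ValueError(f"b-value {b} not present in the result")
    return i
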