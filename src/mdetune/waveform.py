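"""Effective-gradient waveforms for multidimensional diffusion encoding.

A :class:`Waveform` stores the three-axis effective gradient g(t) on a uniform
time grid.  Samples are interpreted as a played-out discrete waveform: each
gradient value is held constant over its dt interval, so the dephasing vector
F(t) = gamma * int g dt is the exact cumulative sum of the samples and is
piecewise linear between grid nodes.  All derived quantities (b-tensor,
spectra, signal predictions) use this convention consistently, which keeps
the echo (refocusing) condition and the b-value identities exact rather than
approximate.

Three encoding types are handled:

* ``isotropic`` — a single-shot waveform whose b-tensor is isotropic
  (q-vector magic-angle spinning and a spectrally balanced variant);
* ``tuned`` — the x-channel of the isotropic encoding scaled by sqrt(3),
  a directional encoding with (nearly) the same encoding power spectrum;
* ``detuned`` — a directional waveform whose scalar dephasing equals the
  dephasing *magnitude* |F(t)| of the isotropic encoding, concentrating
  encoding power at low frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_GRADIENT_CAP, GAMMA_PROTON

__all__ = [
    "Waveform",
    "QmasParams",
    "load_waveform",
    "save_waveform",
    "generate_qmas",
    "generate_balanced_iso",
    "derive_tuned",
    "derive_detuned",
    "scale_to_b",
    "rotate_waveform",
    "fixture_qmas",
]

#: Refocusing tolerance: |sum g dt| <= REFOCUS_RTOL * max|g| * tau per axis.
REFOCUS_RTOL = 1e-9


class WaveformError(ValueError):
    """Raised for malformed or non-refocused gradient waveforms."""


@dataclass(frozen=True)
class Waveform:
    """Time-sampled three-axis effective gradient waveform.

    Parameters
    ----------
    g : ndarray, shape (n, 3)
        Gradient samples in T/m, held piecewise-constant over ``dt``.
    dt : float
        Sample duration in seconds.
    label : str
        Encoding-type tag: ``isotropic``, ``tuned``, ``detuned`` or ``custom``.
    """

    g: np.ndarray
    dt: float
    label: str = "custom"
    gamma: float = field(default=GAMMA_PROTON)

    def __post_init__(self):
        g = np.atleast_2d(np.asarray(self.g, dtype=float))
        if g.ndim != 2 or g.shape[1] != 3:
            raise WaveformError(f"gradient array must have shape (n, 3), got {g.shape}")
        if g.shape[0] < 2:
            raise WaveformError("waveform needs at least 2 samples")
        if not np.isfinite(g).all():
            raise WaveformError("gradient samples must be finite")
        if not (self.dt > 0):
            raise WaveformError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "g", g)

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.g.shape[0]

    @property
    def tau(self) -> float:
        """Encoding duration in seconds (n_samples * dt)."""
        return self.n_samples * self.dt

    @property
    def max_gradient(self) -> float:
        """Largest per-axis gradient magnitude (T/m)."""
        return float(np.abs(self.g).max())

    def exceeds_cap(self, cap: float = DEFAULT_GRADIENT_CAP) -> bool:
        """Whether any sample exceeds the hardware amplitude cap (T/m)."""
        return self.max_gradient > cap

    # -- dephasing ------------------------------------------------------

    def dephasing(self) -> np.ndarray:
        """Dephasing vector F(t) = gamma * int_0^t g, shape (n+1, 3), rad/m.

        Node k holds F at time k*dt; F[0] = 0 and, for a refocused
        waveform, F[-1] = 0 (up to round-off).
        """
        F = np.empty((self.n_samples + 1, 3))
        F[0] = 0.0
        np.cumsum(self.g * (self.gamma * self.dt), axis=0, out=F[1:])
        return F

    def refocusing_residual(self) -> float:
        """Max per-axis |net gradient area| relative to max|g| * tau."""
        net = np.abs(self.g.sum(axis=0) * self.dt)
        scale = self.max_gradient * self.tau
        if scale == 0.0:
            return 0.0
        return float(net.max() / scale)

    def validate(self) -> "Waveform":
        """Check the echo condition; raise :class:`WaveformError` if violated."""
        if self.refocusing_residual() > REFOCUS_RTOL:
            raise WaveformError(
                "waveform violates the refocusing (echo) condition: net gradient "
                f"area residual {self.refocusing_residual():.3e} exceeds {REFOCUS_RTOL:.0e}; "
                "pass repair=True to remove the per-axis mean"
            )
        return self

    # -- transforms -----------------------------------------------------

    def with_label(self, label: str) -> "Waveform":
        return replace(self, label=label)

    def resampled(self, dt_new: float) -> "Waveform":
        """Resample to a finer grid by linear interpolation of F(t).

        The piecewise-linear dephasing is sampled on the new grid and
        differenced back to gradient values, so the resampled waveform has
        identical dephasing at shared nodes and remains exactly refocused.
        """
        n_new = int(round(self.tau / dt_new))
        if abs(n_new * dt_new - self.tau) > 1e-9 * self.tau:
            raise WaveformError("dt_new must divide the encoding duration")
        t_old = np.arange(self.n_samples + 1) * self.dt
        t_new = np.arange(n_new + 1) * dt_new
        F_old = self.dephasing()
        F_new = np.column_stack([np.interp(t_new, t_old, F_old[:, i]) for i in range(3)])
        g_new = np.diff(F_new, axis=0) / (self.gamma * dt_new)
        return replace(self, g=g_new, dt=dt_new)

    def time_stretched(self, factor: float) -> "Waveform":
        """Stretch the encoding in time by ``factor`` (same samples, dt*factor)."""
        if factor <= 0:
            raise WaveformError("stretch factor must be positive")
        return replace(self, dt=self.dt * factor)


@dataclass(frozen=True)
class QmasParams:
    """Parameters for isotropic-encoding waveform generation.

    The cone (q-MAS) generator sweeps the q-vector on a cone at the magic
    angle zeta = arccos(1/sqrt(3)) with envelope a(t) and azimuth psi(t);
    the spectrally balanced generator distributes three orthogonal chirps
    over adjacent harmonics so the per-axis encoding power spectra are
    nearly identical (see :func:`generate_balanced_iso`).
    """

    tau: float = 23e-3
    n_samples: int = 1150
    q_magnitude_profile: str = "sin2"
    azimuthal_rate_rule: str = "a2"
    n_turns: int = 4
    b_value: float = 1e9  # s/m^2 (1000 s/mm^2)
    max_gradient: float | None = None  # enforce cap (T/m) when given

    def __post_init__(self):
        if not (self.tau > 0):
            raise WaveformError("tau must be positive")
        if self.n_samples < 64:
            raise WaveformError("n_samples must be at least 64")
        if self.q_magnitude_profile != "sin2":
            raise WaveformError(f"unknown envelope {self.q_magnitude_profile!r}")
        if self.azimuthal_rate_rule not in ("a2", "constant"):
            raise WaveformError(f"unknown azimuthal rule {self.azimuthal_rate_rule!r}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_waveform(source, dt: float | None = None, label: str = "custom",
                  repair: bool = False) -> Waveform:
    """Read a waveform from a delimited text stream or path.

    The dialect is whitespace- or comma-delimited numeric rows with three
    columns (or one column, promoted to a single-axis waveform on x).
    ``#`` lines are comments; a header line ``# dt = <seconds>`` supplies
    the time step when ``dt`` is not given.

    Parameters
    ----------
    repair : bool
        Remove the per-axis mean gradient when the echo condition is
        violated (e.g. by a constant offset) instead of raising.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    rows = []
    header_dt = None
    header_label = None
    for ln_no, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip().lower()
                if key == "dt":
                    header_dt = float(val)
                elif key == "label":
                    header_label = val.strip()
            continue
        parts = stripped.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise WaveformError(f"line {ln_no}: malformed numeric row: {stripped!r}")
        if len(vals) not in (1, 3):
            raise WaveformError(f"line {ln_no}: expected 1 or 3 columns, got {len(vals)}")
        rows.append(vals)
    if not rows:
        raise WaveformError("empty waveform file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise WaveformError("inconsistent column count across rows")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] == 1:
        arr = np.column_stack([arr[:, 0], np.zeros(len(arr)), np.zeros(len(arr))])
    dt = dt if dt is not None else header_dt
    if dt is None:
        raise WaveformError("time step dt not given and not found in header")
    if repair:
        scale_ref = np.abs(arr).max()
        arr = arr - arr.mean(axis=0)
        arr[np.abs(arr) < 1e-12 * scale_ref] = 0.0  # strip subtraction round-off
    w = Waveform(arr, dt, label=label if header_label is None else header_label)
    return w.validate()


def save_waveform(w: Waveform, target) -> None:
    """Write a waveform as delimited text with a ``#`` header carrying dt."""
    header = (f"# effective gradient waveform, unit = T/m\n"
              f"# dt = {w.dt:.12e}\n"
              f"# label = {w.label}\n")
    body = "\n".join(" ".join(f"{v: .9e}" for v in row) for row in w.g)
    text = header + body + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _envelope_and_phase(tau: float, n_samples: int):
    """sin^2 envelope a(t) at nodes plus the a^2-time coordinate s(t).

    s(t) is the fraction of integral of a^2 accumulated up to t; azimuthal
    rules proportional to a^2 become linear in s, which makes chirps at
    distinct integer turn counts exactly orthogonal under the a^2 weight.
    """
    t = np.linspace(0.0, tau, n_samples + 1)
    a = np.sin(np.pi * t / tau) ** 2
    a2 = a * a
    cum = np.concatenate([[0.0], np.cumsum((a2[1:] + a2[:-1]) * 0.5)])
    s = cum / cum[-1]
    return t, a, s


def _waveform_from_dephasing(F: np.ndarray, dt: float, label: str,
                             gamma: float = GAMMA_PROTON) -> Waveform:
    """Build a waveform whose node dephasing is exactly ``F`` (shape (n+1, 3))."""
    g = np.diff(F, axis=0) / (gamma * dt)
    return Waveform(g, dt, label=label, gamma=gamma)


def _symmetrize_isotropic(F: np.ndarray, dt: float) -> np.ndarray:
    """Apply the linear map that makes the discrete b-tensor exactly isotropic.

    For M = int F F^T dt (piecewise-linear exact), the transform
    L = sqrt(tr M / 3) * M^(-1/2) gives int (LF)(LF)^T dt = (tr M / 3) I.
    For a well-designed input M is already near-isotropic and L is near the
    identity, so per-axis spectra are essentially unchanged.
    """
    from .spectral import _pl_outer_integral

    M = _pl_outer_integral(F, dt)
    evals, evecs = np.linalg.eigh(M)
    if evals.min() <= 0:
        raise WaveformError("degenerate dephasing trajectory; cannot symmetrize")
    L = (evecs * (np.sqrt(M.trace() / 3.0) / np.sqrt(evals))) @ evecs.T
    return F @ L.T


def _cone_dephasing(p: QmasParams) -> tuple[np.ndarray, float]:
    """Dephasing of the magic-angle cone sweep at sample nodes."""
    dt = p.tau / p.n_samples
    t, a, s = _envelope_and_phase(p.tau, p.n_samples)
    if p.azimuthal_rate_rule == "a2":
        psi = 2.0 * np.pi * p.n_turns * s
    else:  # constant spinning rate
        psi = 2.0 * np.pi * p.n_turns * t / p.tau
    sin_z = np.sqrt(2.0 / 3.0)
    cos_z = np.sqrt(1.0 / 3.0)
    F = np.column_stack([a * sin_z * np.cos(psi), a * sin_z * np.sin(psi), a * cos_z])
    return F, dt


def generate_qmas(p: QmasParams) -> Waveform:
    """Magic-angle-spinning isotropic encoding (cone construction).

    The dephasing vector follows
    ``q(t) = q0 a(t) [sin z cos psi, sin z sin psi, cos z]`` with the cone
    polar angle fixed at the magic angle z = arccos(1/sqrt(3)), envelope
    a(t) = sin^2(pi t / tau) and azimuthal rate dpsi/dt either proportional
    to a(t)^2 (rule ``a2``) or constant (rule ``constant``), winding n_turns
    full revolutions.  The discrete b-tensor is made exactly isotropic by a
    near-identity linear symmetrization.

    Note: with the cone axis on the laboratory z axis this construction has
    pronounced spectral anisotropy (the z-axis encoding power is the
    envelope spectrum, near DC); use :func:`generate_balanced_iso` when
    per-axis spectral similarity matters.
    """
    F, dt = _cone_dephasing(p)
    F = _symmetrize_isotropic(F, dt)
    w = _waveform_from_dephasing(F, dt, label="isotropic")
    w = scale_to_b(w, p.b_value) if p.b_value > 0 else w
    _check_cap(w, p.max_gradient)
    return w


#: rotation taking the cone axis (z) onto the (1,1,1)/sqrt(3) direction
_BALANCE_ROTATION = None


def _balance_rotation() -> np.ndarray:
    global _BALANCE_ROTATION
    if _BALANCE_ROTATION is None:
        target = np.full(3, 1.0 / np.sqrt(3.0))
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, target)
        c = float(z @ target)
        vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
        _BALANCE_ROTATION = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return _BALANCE_ROTATION


def generate_balanced_iso(p: QmasParams | None = None) -> Waveform:
    """Spectrally balanced isotropic encoding (rotated constant-rate cone).

    The magic-angle cone sweep separates spectrally into a low-frequency
    envelope band (carried by the cone axis, 1/3 of the power) and, with a
    constant spinning rate, a narrow rotation band at n_turns/tau Hz
    (carried by the transverse axes, 2/3 of the power).  Rotating the cone
    axis onto the (1,1,1)/sqrt(3) body diagonal distributes both bands
    equally over the three laboratory axes, so the per-axis encoding power
    spectra are nearly identical — the property that makes the
    sqrt(3)-scaled x-channel a spectrally *tuned* directional encoding.

    With the sin^2 envelope (whose squared magnitude has Fourier support on
    harmonics 0, 1, 2 of 1/tau only) a constant rate of n_turns >= 3 integer
    revolutions makes the continuum b-tensor exactly isotropic; residual
    discretisation anisotropy is removed by the linear symmetrization.
    """
    if p is None:
        p = QmasParams(azimuthal_rate_rule="constant")
    if p.azimuthal_rate_rule == "constant" and p.n_turns < 3:
        raise WaveformError("constant-rate cone needs n_turns >= 3 for isotropy")
    if p.azimuthal_rate_rule != "constant":
        p = QmasParams(tau=p.tau, n_samples=p.n_samples,
                       q_magnitude_profile=p.q_magnitude_profile,
                       azimuthal_rate_rule="constant", n_turns=p.n_turns,
                       b_value=p.b_value, max_gradient=p.max_gradient)
    F, dt = _cone_dephasing(p)
    F = F @ _balance_rotation().T
    F = _symmetrize_isotropic(F, dt)
    w = _waveform_from_dephasing(F, dt, label="isotropic")
    w = scale_to_b(w, p.b_value) if p.b_value > 0 else w
    _check_cap(w, p.max_gradient)
    return w


def _check_cap(w: Waveform, cap: float | None) -> None:
    if cap is not None and w.max_gradient > cap:
        idx = int(np.abs(w.g).max(axis=1).argmax())
        raise WaveformError(
            f"gradient amplitude {w.max_gradient * 1e3:.1f} mT/m at sample {idx} "
            f"exceeds the cap {cap * 1e3:.1f} mT/m"
        )


# ---------------------------------------------------------------------------
# derivations and transforms
# ---------------------------------------------------------------------------

def derive_tuned(iso: Waveform) -> Waveform:
    """Spectrally tuned directional encoding: x-channel scaled by sqrt(3).

    The scaling matches the b-value of the isotropic parent exactly when
    the per-axis encoding powers are equal (they are, by construction, for
    the symmetrized generators).  Applying this twice scales b by 3 again;
    that is a caller error, not a checked condition.
    """
    if iso.label != "isotropic":
        raise WaveformError("derive_tuned expects a waveform labelled 'isotropic'")
    g = np.zeros_like(iso.g)
    g[:, 0] = iso.g[:, 0] * np.sqrt(3.0)
    return replace(iso, g=g, label="tuned")


def derive_detuned(iso: Waveform) -> Waveform:
    """Spectrally detuned directional encoding from the dephasing magnitude.

    The scalar dephasing is F_d(t) = |F(t)| of the isotropic parent; the
    gradient is its exact discrete derivative on the sample grid (forward
    differences of the node values, matching the piecewise-constant
    convention).  Because |F| is integrated with the same quadrature, the
    detuned b-value equals the parent trace(b) to round-off.  |F(t)| of an
    isotropic encoding varies on the envelope time-scale, which concentrates
    encoding power at low frequencies.
    """
    if iso.label != "isotropic":
        raise WaveformError("derive_detuned expects a waveform labelled 'isotropic'")
    F = iso.dephasing()
    Fd = np.linalg.norm(F, axis=1)
    F_new = np.column_stack([Fd, np.zeros_like(Fd), np.zeros_like(Fd)])
    return _waveform_from_dephasing(F_new, iso.dt, "detuned", iso.gamma)


def scale_to_b(w: Waveform, b_target: float) -> Waveform:
    """Scale gradient amplitudes so that trace(b) equals ``b_target`` (s/m^2)."""
    from .spectral import b_tensor

    if b_target < 0:
        raise WaveformError("b_target must be non-negative")
    if b_target == 0:
        return replace(w, g=np.zeros_like(w.g))
    b_now = b_tensor(w).b
    if b_now == 0:
        raise WaveformError("cannot scale a zero waveform to a positive b-value")
    return replace(w, g=w.g * np.sqrt(b_target / b_now))


def rotate_waveform(w: Waveform, rotation: np.ndarray) -> Waveform:
    """Rotate the gradient axes; the b-tensor maps to R b R^T, trace invariant."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise WaveformError("rotation must be a 3x3 orthonormal matrix")
    return replace(w, g=w.g @ R.T)


# ---------------------------------------------------------------------------
# shipped fixture
# ---------------------------------------------------------------------------

#: Frozen parameters of the shipped isotropic fixture (tau = 23 ms).
FIXTURE_PARAMS = QmasParams(tau=23e-3, n_samples=1150, n_turns=4,
                            azimuthal_rate_rule="constant", b_value=1e9)


def fixture_qmas() -> Waveform:
    """Load the shipped spectrally balanced isotropic fixture (tau = 23 ms).

    The file under ``mdetune/data`` was written by
    ``generate_balanced_iso(FIXTURE_PARAMS)``; loading it rather than
    regenerating keeps every downstream number tied to one immutable
    waveform.
    """
    from importlib.resources import files

    path = files("mdetune").joinpath("data/qmas_balanced_tau23ms.txt")
    with io.StringIO(path.read_text()) as fh:
        return load_waveform(fh, label="isotropic")
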