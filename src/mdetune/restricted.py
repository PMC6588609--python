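"""Diffusion spectra for restricted and Gaussian compartments.

Restricted diffusion between reflecting barriers has a velocity-correlation
spectrum that is a sum of Lorentzian-complement modes,

    lambda(w) = sum_k B_k a_k w^2 / (a_k^2 + w^2),

with relaxation rates a_k = alpha_k^2 D0 / R^2 set by the dimensionless
eigenvalue roots alpha_k of the geometry and weights B_k (m^2).  The spectrum
vanishes at w = 0 (fully restricted long-time limit), rises monotonically
with |w| and saturates at the intrinsic diffusivity D0 (completeness:
sum_k B_k a_k = D0).

Geometries (R is the radius, or half-separation for plates at +-R):

* plane:    alpha_k = (2k-1) pi / 2,       B_k = 32 R^2 / ((2k-1)^4 pi^4)
* cylinder: alpha_k roots of J1'(alpha),   B_k = 2 (R^2/alpha_k^2) / (alpha_k^2 - 1)
* sphere:   alpha_k roots of j1'(alpha),   B_k = 2 (R^2/alpha_k^2) / (alpha_k^2 - 2)

An orientable compartment is a :class:`DiffusionModel`: per-principal-axis
spectra lambda_i(w) plus a rotation, giving D(w) = R diag(lambda) R^T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import jvp

__all__ = [
    "GeometryEigenmodes",
    "DiffusionModel",
    "eigenmode_table",
    "lambda_spectrum",
    "make_model",
    "parse_model_spec",
]

GEOMETRIES = ("plane", "cylinder", "sphere")

#: completeness requirement on sum B_k a_k / D0 at the default truncation
COMPLETENESS_RTOL = 1e-3


def _j1p_spherical(x: np.ndarray | float):
    """Derivative-of-j1 root function: (x^2 - 2) sin x + 2 x cos x (~ x^3 j1'(x))."""
    return (x * x - 2.0) * np.sin(x) + 2.0 * x * np.cos(x)


def _bessel_roots(func, K: int, x_max_hint: float) -> np.ndarray:
    """First K positive roots of ``func`` by sign-change scan plus brentq."""
    roots = []
    x = 0.5
    step = 0.05
    f_prev = func(x)
    while len(roots) < K:
        x_next = x + step
        f_next = func(x_next)
        if f_prev == 0.0:
            roots.append(x)
        elif np.sign(f_prev) != np.sign(f_next):
            roots.append(brentq(func, x, x_next, xtol=1e-12, rtol=8.9e-16))
        x, f_prev = x_next, f_next
        if x > x_max_hint * (K + 5):
            raise RuntimeError("root scan failed to bracket enough roots")
    return np.asarray(roots[:K])


@dataclass(frozen=True)
class GeometryEigenmodes:
    """Eigenmode expansion of a restricted geometry's diffusion spectrum."""

    geometry: str
    roots: np.ndarray       # dimensionless alpha_k, strictly increasing
    weights: np.ndarray     # B_k in m^2
    R: float
    D0: float

    @property
    def K(self) -> int:
        return len(self.roots)

    @property
    def rates(self) -> np.ndarray:
        """Relaxation rates a_k = alpha_k^2 D0 / R^2 (1/s)."""
        return self.roots ** 2 * self.D0 / self.R ** 2

    @property
    def completeness(self) -> float:
        """sum B_k a_k / D0; tends to 1 as K grows (high-frequency limit)."""
        return float((self.weights * self.rates).sum() / self.D0)


def eigenmode_table(geometry: str, R: float, D0: float, K: int = 50,
                    tail: bool = True) -> GeometryEigenmodes:
    """Roots and weights of the restricted-diffusion spectrum expansion.

    The weight sums obey exact sum rules (sum_k 2/(alpha_k^2 - 1) = 1 for the
    cylinder, sum_k 2/(alpha_k^2 - 2) = 1 for the sphere, sum over odd j of
    8/(j pi)^2 = 1 for the plane), but the partial sums converge only like
    1/K.  With ``tail=True`` (default) the truncation residual is carried by
    one extra mode at the asymptotic continuation of the root sequence
    (alpha_K + pi), which restores the exact high-frequency limit
    lambda(inf) = D0 while leaving the spectrum in any band below the first
    omitted rate a_{K+1} = alpha_{K+1}^2 D0 / R^2 unchanged to O(1/alpha^4).
    Warns if the completeness residual still exceeds 1e-3.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}, got {geometry!r}")
    if R <= 0 or D0 <= 0 or K < 1:
        raise ValueError("require R > 0, D0 > 0, K >= 1")
    if geometry == "plane":
        k = np.arange(1, K + 1)
        roots = (2 * k - 1) * np.pi / 2.0
        weights = 32.0 * R ** 2 / ((2 * k - 1) ** 4 * np.pi ** 4)
    elif geometry == "cylinder":
        roots = _bessel_roots(lambda x: jvp(1, x), K, np.pi)
        weights = 2.0 * (R ** 2 / roots ** 2) / (roots ** 2 - 1.0)
    else:  # sphere
        roots = _bessel_roots(_j1p_spherical, K, np.pi)
        weights = 2.0 * (R ** 2 / roots ** 2) / (roots ** 2 - 2.0)
    if tail:
        ba_partial = (weights * roots ** 2 / R ** 2).sum()  # sum B_k a_k / D0
        resid = 1.0 - ba_partial
        if resid > 0:
            alpha_t = roots[-1] + np.pi
            roots = np.append(roots, alpha_t)
            weights = np.append(weights, resid * R ** 2 / alpha_t ** 2)
    modes = GeometryEigenmodes(geometry, roots, weights, R, D0)
    resid = abs(modes.completeness - 1.0)
    if resid > COMPLETENESS_RTOL:
        warnings.warn(
            f"{geometry} eigenmode table at K={K} misses the high-frequency limit "
            f"by {resid:.2e} (> {COMPLETENESS_RTOL:.0e}); increase K",
            stacklevel=2,
        )
    return modes


def lambda_spectrum(modes: GeometryEigenmodes, omega: np.ndarray) -> np.ndarray:
    """Restricted diffusion spectrum lambda(w) on a frequency grid (rad/s).

    Monotone non-decreasing in |w|, zero at w = 0, saturating at D0 (up to
    the truncation residual).  Depends on (R, D0, w) only through the
    dimensionless product w R^2 / D0.
    """
    w2 = np.asarray(omega, dtype=float) ** 2
    a = modes.rates
    Ba = modes.weights * a
    return (Ba[:, None] * (w2[None, :] / (a[:, None] ** 2 + w2[None, :]))).sum(axis=0)


@dataclass(frozen=True)
class DiffusionModel:
    """Orientable compartment: principal diffusion spectra plus a rotation.

    ``kind`` is ``restricted`` (sphere/cylinder/plane eigenmode spectra on
    the restricted axes, flat D0 on free axes) or ``gaussian_tensor`` (flat
    per-axis spectra equal to the tensor eigenvalues).  ``rotation`` columns
    are the principal axes expressed in the laboratory frame; the lab-frame
    spectrum is D(w) = R diag(lambda_i(w)) R^T.  For cylinders the symmetry
    (free) axis is the third principal axis; for planes the restricted axis
    is the third.
    """

    kind: str
    geometry: str | None
    modes: GeometryEigenmodes | None
    eigenvalues: tuple[float, float, float] | None
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    D0: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", R)

    def rotated(self, extra: np.ndarray) -> "DiffusionModel":
        """Compose an additional laboratory-frame rotation."""
        from dataclasses import replace

        return replace(self, rotation=np.asarray(extra) @ self.rotation)

    def axis_spectra(self, omega: np.ndarray) -> np.ndarray:
        """Principal-axis spectra lambda_i(w), shape (3, len(omega))."""
        omega = np.asarray(omega, dtype=float)
        out = np.empty((3, omega.size))
        if self.kind == "gaussian_tensor":
            for i, ev in enumerate(self.eigenvalues):
                out[i] = ev
            return out
        lam = lambda_spectrum(self.modes, omega)
        if self.geometry == "sphere":
            out[:] = lam
        elif self.geometry == "cylinder":
            out[0] = lam
            out[1] = lam
            out[2] = self.D0
        else:  # plane: one restricted axis (third), two free
            out[0] = self.D0
            out[1] = self.D0
            out[2] = lam
        return out


def make_model(geometry: str | None = None, R: float | None = None,
               D0: float | None = None, rotation: np.ndarray | None = None,
               eigenvalues=None, K: int = 50) -> DiffusionModel:
    """Build an orientable diffusion model.

    Either a restricted geometry (``geometry``, ``R``, ``D0``) or a Gaussian
    tensor (``eigenvalues``, optionally anisotropic) must be given.  ``free``
    with diffusivity D0 is shorthand for an isotropic Gaussian tensor.
    """
    rot = np.eye(3) if rotation is None else rotation
    if eigenvalues is not None:
        ev = tuple(float(e) for e in eigenvalues)
        if len(ev) != 3 or any(e < 0 for e in ev):
            raise ValueError("need three non-negative tensor eigenvalues")
        return DiffusionModel("gaussian_tensor", None, None, ev, rot, D0=max(ev))
    if geometry == "free":
        if D0 is None or D0 < 0:
            raise ValueError("free model needs a non-negative D0")
        return DiffusionModel("gaussian_tensor", None, None, (D0, D0, D0), rot, D0=D0)
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}")
    if R is None or D0 is None:
        raise ValueError("restricted model needs R and D0")
    modes = eigenmode_table(geometry, R, D0, K=K)
    return DiffusionModel("restricted", geometry, modes, None, rot, D0=D0)


def parse_model_spec(spec: str) -> tuple[DiffusionModel, float]:
    """Parse a compact model spec, returning (model, signal fraction).

    Examples: ``sphere:R=2.5e-6,D0=1e-9``, ``cylinder:R=5e-6,D0=1e-9,frac=0.5``,
    ``tensor:eigs=1e-9,0,0``, ``free:D0=2e-9``, optional ``rot=euler:a,b,c``
    (intrinsic z-y-z angles in radians).
    """
    from scipy.spatial.transform import Rotation

    kind, _, rest = spec.partition(":")
    kind = kind.strip().lower()
    params: dict[str, str] = {}
    if rest:
        # split on commas not following '=' of a multi-valued key (eigs, rot)
        tokens = rest.split(",")
        key = None
        for tok in tokens:
            if "=" in tok:
                key, _, val = tok.partition("=")
                params[key.strip()] = val.strip()
            elif key is not None:
                params[key.strip()] += "," + tok.strip()
            else:
                raise ValueError(f"malformed model spec {spec!r}")
    frac = float(params.pop("frac", 1.0))
    rot = None
    if "rot" in params:
        scheme, _, angles = params.pop("rot").partition(":")
        if scheme != "euler":
            raise ValueError(f"unknown rotation scheme {scheme!r}")
        a, b, c = (float(x) for x in angles.split(","))
        rot = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
    if kind == "tensor":
        eigs = [float(x) for x in params.pop("eigs").split(",")]
        model = make_model(eigenvalues=eigs, rotation=rot)
    elif kind == "free":
        model = make_model(geometry="free", D0=float(params.pop("D0")), rotation=rot)
    else:
        model = make_model(geometry=kind, R=float(params.pop("R")),
                           D0=float(params.pop("D0")), rotation=rot,
                           K=int(params.pop("K", 50)))
    if params:
        raise ValueError(f"unrecognised keys in model spec: {sorted(params)}")
    return model, frac
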