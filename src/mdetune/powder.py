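"""Orientation sets, powder averaging and cumulant statistics.

Powder averaging — the arithmetic mean of signals over uniformly distributed
encoding orientations — emulates a uniformly dispersed microstructure in any
sample.  The orientation dependence of the apparent diffusion coefficient is
summarised by its mean <ADC> and population variance V_D, which give the
second-cumulant powder signal E(b) = exp(-<ADC> b + V_D b^2 / 2): <ADC> sets
the initial slope of ln E vs b and V_D its curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "OrientationSet",
    "SignalCurve",
    "AdcMoments",
    "orientation_set",
    "powder_average",
    "adc_moments",
    "cumulant_signal",
    "fit_cumulant3",
]


@dataclass(frozen=True)
class OrientationSet:
    """N orthonormal frames; ``rotations[i]`` maps local z to ``directions[i]``."""

    directions: np.ndarray   # (n, 3)
    rotations: np.ndarray    # (n, 3, 3), right-handed
    scheme: str
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.directions)


def _frames_from_directions(dirs: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frames with third column = direction.

    The in-plane axes are spun about each direction by a deterministic
    golden-angle-like sequence (increment 2*pi*frac(sqrt(2))), so that for a
    quasi-uniform direction set the first and second columns also cover the
    sphere quasi-uniformly — the frame set approximates a uniform sample of
    SO(3), not just of directions.
    """
    n = len(dirs)
    frames = np.empty((n, 3, 3))
    aux = np.where(np.abs(dirs[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    u = np.cross(aux, dirs)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(dirs, u)
    spin = 2.0 * np.pi * ((np.arange(n) * (np.sqrt(2.0) - 1.0)) % 1.0)
    c, s = np.cos(spin)[:, None], np.sin(spin)[:, None]
    frames[:, :, 0] = c * u + s * v
    frames[:, :, 1] = -s * u + c * v
    frames[:, :, 2] = dirs
    return frames


def orientation_set(n: int, scheme: str = "fibonacci",
                    seed: int | None = None) -> OrientationSet:
    """Uniformly distributed orientations on the sphere.

    ``fibonacci`` is the deterministic spherical Fibonacci lattice (for
    n = 1000 directional means of linear functionals match sphere integrals
    to ~1e-3); ``random`` draws isotropic directions from ``seed``.  n = 1
    returns the identity frame.
    """
    if n < 1:
        raise ValueError("need n >= 1 orientations")
    if n == 1:
        dirs = np.array([[0.0, 0.0, 1.0]])
        return OrientationSet(dirs, np.eye(3)[None], scheme, seed)
    if scheme == "fibonacci":
        k = np.arange(n)
        golden = (1.0 + np.sqrt(5.0)) / 2.0
        z = 1.0 - (2.0 * k + 1.0) / n
        phi = 2.0 * np.pi * k / golden
        rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown orientation scheme {scheme!r}")
    return OrientationSet(dirs, _frames_from_directions(dirs), scheme, seed)


@dataclass(frozen=True)
class SignalCurve:
    """Attenuation versus b for one encoding type.

    ``b`` in s/m^2; ``E`` normalised so that E(b=0) = 1; ``provenance`` is
    ``analytic``, ``mc`` or ``synthetic-noisy``.
    """

    b: np.ndarray
    E: np.ndarray
    label: str
    n_orientations: int = 1
    provenance: str = "analytic"

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if b.shape != E.shape:
            raise ValueError("b and E must have matching shapes")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "E", E)

    def at_b(self, b_star: float) -> float:
        i = int(np.argmin(np.abs(self.b - b_star)))
        if abs(self.b[i] - b_star) > 1e-6 * max(abs(b_star), 1.0):
            raise ValueError(f"b = {b_star} not present in this curve")
        return float(self.E[i])


@dataclass(frozen=True)
class AdcMoments:
    """Mean and population variance of ADC over orientations."""

    mean: float      # m^2/s
    variance: float  # m^4/s^2


def powder_average(curves: list[SignalCurve]) -> SignalCurve:
    """Arithmetic mean of per-orientation attenuations on a common b grid."""
    if not curves:
        raise ValueError("no curves to average")
    b0 = curves[0].b
    for c in curves[1:]:
        if c.b.shape != b0.shape or not np.allclose(c.b, b0, rtol=1e-10):
            raise ValueError("curves must share the same b grid")
    E = np.mean([c.E for c in curves], axis=0)
    return SignalCurve(b0, E, curves[0].label,
                       n_orientations=sum(c.n_orientations for c in curves),
                       provenance=curves[0].provenance)


def adc_moments(adcs: np.ndarray) -> AdcMoments:
    """<ADC> and V_D = <(ADC - <ADC>)^2> over the orientation set.

    Population (not sample) variance: the orientation set is the full
    design, not a random sample from it.
    """
    a = np.asarray(adcs, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one ADC value")
    return AdcMoments(float(a.mean()), float(a.var()))


def cumulant_signal(m: AdcMoments, b_grid: np.ndarray) -> SignalCurve:
    """Second-cumulant powder signal exp(-<ADC> b + V_D b^2 / 2)."""
    b = np.asarray(b_grid, dtype=float)
    E = np.exp(-m.mean * b + 0.5 * m.variance * b * b)
    return SignalCurve(b, E, "cumulant")


def _cumulant3(b, S0, c1, c2, c3):
    return S0 * np.exp(-c1 * b + 0.5 * c2 * b ** 2 - c3 * b ** 3 / 6.0)


def fit_cumulant3(b: np.ndarray, S: np.ndarray) -> dict:
    """Nonlinear least-squares fit of S = S0 exp(-c1 b + c2 b^2/2 - c3 b^3/6).

    The unweighted signal S0 is a free parameter, so a b = 0 sample is not
    required.  Initial values come from a cubic polynomial fit to ln S.
    Returns S0, c1, c2, c3 and the residual root-mean-square.
    """
    b = np.asarray(b, dtype=float)
    S = np.asarray(S, dtype=float)
    if b.size < 5:
        raise ValueError("need at least 5 samples for the 3rd-order fit")
    if np.any(S <= 0):
        raise ValueError("signals must be positive")
    # initial guess from log-domain polynomial
    coef = np.polyfit(b, np.log(S), 3)
    p0 = [float(np.exp(coef[3])), float(-coef[2]), float(2.0 * coef[1]),
          float(-6.0 * coef[0])]
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # exact synthetic data yields a singular covariance; irrelevant here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_cumulant3, b, S, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"3rd-order cumulant fit failed to converge: {err}; "
            f"initial guess was {p0}"
        ) from err
    resid = S - _cumulant3(b, *popt)
    return {"S0": float(popt[0]), "c1": float(popt[1]), "c2": float(popt[2]),
            "c3": float(popt[3]), "rms_residual": float(np.sqrt(np.mean(resid ** 2)))}
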