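"""Spherically averaged neutral reference proatom densities.

A proatom is the reference density shape for one atom in a molecule: a
positive, monotonically decaying spherical function rho0(r) with a known
electron population n0 = integral of rho0 over all space. The built-in
library represents each element Z = 1-36 by a sum of s-type Gaussian shells

    rho0(r) = sum_j a_j * exp(-alpha_j * r^2)

normalized so that n0 = Z exactly. Gaussians are used (rather than, say,
Slater functions) because the population, the dipole and the electrostatic
potential of a spherical Gaussian shell all have closed forms, which the
grid and electrostatics modules use as analytic oracles. These are *model*
proatoms: their shapes are not fitted to real atomic densities. Users who
need realistic proatoms can supply radial tables (see ``TabulatedProatom``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.interpolate import CubicSpline

from .elements import ANGSTROM_TO_BOHR, MAX_Z, VDW_RADII_ANGSTROM, symbol

__all__ = [
    "RadialProatom",
    "ScaledProatom",
    "TabulatedProatom",
    "build_neutral_proatom",
    "evaluate_proatom",
    "proatom_population",
    "read_radial_table",
]


@dataclass(frozen=True)
class RadialProatom:
    """Neutral spherical reference density as a sum of Gaussian shells.

    Parameters
    ----------
    atomic_number
        Nuclear charge Z of the element this proatom represents.
    amplitudes, exponents
        Shell parameters a_j (electrons/bohr^3) and alpha_j (1/bohr^2),
        all strictly positive so the density is positive everywhere.
    """

    atomic_number: int
    amplitudes: np.ndarray
    exponents: np.ndarray

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        e = np.atleast_1d(np.asarray(self.exponents, dtype=float))
        if a.shape != e.shape or a.ndim != 1:
            raise ValueError("amplitudes and exponents must be 1-D and matched")
        if np.any(a <= 0) or np.any(e <= 0):
            raise ValueError("shell amplitudes and exponents must be positive")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "exponents", e)

    @property
    def population(self) -> float:
        """Reference population n0 = sum_j a_j (pi/alpha_j)^{3/2}."""
        return float(np.sum(self.amplitudes * (np.pi / self.exponents) ** 1.5))

    def evaluate(self, distances) -> np.ndarray:
        """Density at radial distances (bohr) from the nucleus."""
        r = np.asarray(distances, dtype=float)
        if np.any(r < 0):
            raise ValueError("distances must be nonnegative")
        r2 = r[..., None] ** 2
        return np.sum(self.amplitudes * np.exp(-self.exponents * r2), axis=-1)


@dataclass(frozen=True)
class ScaledProatom:
    """A proatom placed at a nuclear center and scaled by a coefficient c > 0.

    The scaled density is c * rho0(|r - center|), so its population is
    c * n0 exactly.
    """

    base: RadialProatom
    center: np.ndarray
    coefficient: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        if not self.coefficient > 0:
            raise ValueError("scaling coefficient must be positive")

    @property
    def population(self) -> float:
        return self.coefficient * self.base.population

    def evaluate(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        r = np.linalg.norm(pts.reshape(-1, 3) - self.center, axis=1)
        out = self.coefficient * self.base.evaluate(r)
        return out.reshape(pts.shape[:-1])


# Built-in library shape parameters. The tightest exponent scales as
# Z^{4/3} (core contraction with nuclear charge); the most diffuse exponent
# is set from the element's van der Waals radius so the atomic density is
# negligible (< ~1e-7 e/bohr^3) on the 2.5-scaled vdW surface, as real
# atomic densities are. Intermediate shells interpolate geometrically.
_CORE_EXPONENT = 2.0
_TAIL_ERF_ARG = 4.0  # sqrt(alpha_min) * (2.5 r_vdw) >= this
_FALLBACK_VDW_BOHR = 2.0 / 0.529177210903


def _exponent_range(z: int) -> tuple[float, float]:
    r_vdw = VDW_RADII_ANGSTROM.get(symbol(z))
    r_vdw = r_vdw * ANGSTROM_TO_BOHR if r_vdw is not None else _FALLBACK_VDW_BOHR
    alpha_max = _CORE_EXPONENT * z ** (4.0 / 3.0)
    alpha_min = (_TAIL_ERF_ARG / (2.5 * r_vdw)) ** 2
    return alpha_max, min(alpha_min, 0.5 * alpha_max)


def build_neutral_proatom(atomic_number: int, n_shells: int = 3) -> RadialProatom:
    """Deterministic model proatom for element Z with exactly Z electrons.

    Exponents form a geometric progression from a Z^{4/3}-scaled core value
    down to a vdW-radius-derived diffuse value; each shell is normalized to
    carry an equal share of the Z electrons, so the population is Z exactly.
    """
    z = int(atomic_number)
    if not 1 <= z <= MAX_Z:
        raise ValueError(f"unsupported element: Z={atomic_number} (supported 1-{MAX_Z})")
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    alpha_max, alpha_min = _exponent_range(z)
    if n_shells == 1:
        exponents = np.array([np.sqrt(alpha_max * alpha_min)])
    else:
        exponents = np.geomspace(alpha_max, alpha_min, n_shells)
    per_shell = z / n_shells
    amplitudes = per_shell * (exponents / np.pi) ** 1.5
    return RadialProatom(z, amplitudes, exponents)


def evaluate_proatom(p, distances) -> np.ndarray:
    """Pointwise density of a proatom at the given radial distances (bohr)."""
    return p.evaluate(distances)


def proatom_population(p) -> float:
    """Closed-form population n0 of a (possibly tabulated) proatom."""
    return p.population


class TabulatedProatom:
    """Proatom defined by a user-supplied radial table (r, rho0(r)).

    Interpolates ln(rho) with a cubic spline, which enforces positivity,
    and extrapolates the tail as rho ~ exp(-beta r) using the log-slope at
    the last tabulated point. The population is obtained by radial
    quadrature of 4 pi r^2 rho(r).
    """

    def __init__(self, atomic_number: int, r: np.ndarray, rho: np.ndarray):
        r = np.asarray(r, dtype=float)
        rho = np.asarray(rho, dtype=float)
        if r.ndim != 1 or r.shape != rho.shape or r.size < 4:
            raise ValueError("need matched 1-D arrays with at least 4 points")
        if np.any(np.diff(r) <= 0) or r[0] < 0:
            raise ValueError("radial points must be nonnegative and increasing")
        if np.any(rho <= 0):
            raise ValueError("tabulated densities must be positive")
        self.atomic_number = int(atomic_number)
        self._rmax = r[-1]
        self._spline = CubicSpline(r, np.log(rho))
        beta = -float(self._spline(self._rmax, 1))
        if beta <= 0:
            raise ValueError("tabulated density must decay at the last point")
        self._beta = beta
        self._log_tail = float(self._spline(self._rmax))
        self._population = self._integrate_population()

    def evaluate(self, distances) -> np.ndarray:
        r = np.asarray(distances, dtype=float)
        if np.any(r < 0):
            raise ValueError("distances must be nonnegative")
        r = np.atleast_1d(r)
        out = np.empty_like(r)
        inside = r <= self._rmax
        out[inside] = np.exp(self._spline(r[inside]))
        out[~inside] = np.exp(self._log_tail - self._beta * (r[~inside] - self._rmax))
        return out if np.ndim(distances) else float(out[0])

    @property
    def population(self) -> float:
        return self._population

    def _integrate_population(self) -> float:
        body, _ = integrate.quad(
            lambda rr: 4.0 * np.pi * rr**2 * float(np.exp(self._spline(rr))),
            0.0, self._rmax, limit=200,
        )
        # Analytic tail: 4 pi * integral_{rmax}^inf r^2 A e^{-beta(r-rmax)} dr
        a, b, rm = np.exp(self._log_tail), self._beta, self._rmax
        tail = 4.0 * np.pi * a * (rm**2 / b + 2 * rm / b**2 + 2 / b**3)
        return float(body + tail)


def read_radial_table(path, atomic_number: int) -> TabulatedProatom:
    """Read a two-column text table (r bohr, rho electrons/bohr^3).

    Lines starting with '#' are comments.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (r, rho)")
    return TabulatedProatom(atomic_number, data[:, 0], data[:, 1])
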