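"""Molecular electron-density fields.

A density field is anything with an ``evaluate(points) -> values`` method
(electrons/bohr^3 at Cartesian points in bohr). The workhorse here is
``GaussianShellDensity``: an explicit sum of atom-centered spherical
Gaussian terms. Because every term is spherical, its total population,
dipole moment, and electrostatic potential have closed forms, which the
rest of the package uses as analytic oracles. Individual shell amplitudes
may be negative (deformation terms); the *total* density is expected to be
nonnegative, which the synthetic-data generator enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = ["GaussianShellDensity"]


@dataclass(frozen=True)
class GaussianShellDensity:
    """Sum of spherical Gaussian shells a_s * exp(-alpha_s |r - c_s|^2)."""

    centers: np.ndarray     # (m, 3) bohr
    amplitudes: np.ndarray  # (m,) electrons/bohr^3, sign free
    exponents: np.ndarray   # (m,) 1/bohr^2, > 0

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        e = np.atleast_1d(np.asarray(self.exponents, dtype=float))
        if c.shape != (a.size, 3) or a.shape != e.shape:
            raise ValueError("mismatched shell arrays")
        if np.any(e <= 0):
            raise ValueError("shell exponents must be positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "exponents", e)

    @property
    def shell_populations(self) -> np.ndarray:
        """Electrons per shell: a_s (pi/alpha_s)^{3/2} (signed)."""
        return self.amplitudes * (np.pi / self.exponents) ** 1.5

    @property
    def total_electrons(self) -> float:
        return float(self.shell_populations.sum())

    def evaluate(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 3)
        out = np.zeros(flat.shape[0])
        for c, a, e in zip(self.centers, self.amplitudes, self.exponents):
            d2 = np.sum((flat - c) ** 2, axis=1)
            out += a * np.exp(-e * d2)
        return out.reshape(pts.shape[:-1])

    def dipole(self) -> np.ndarray:
        """Closed-form dipole of the density about the origin.

        Each spherical shell contributes population x center (shell theorem).
        """
        return self.shell_populations @ self.centers

    def coulomb_potential(self, points) -> np.ndarray:
        """Closed-form Coulomb potential generated by the density.

        Treats the density as positive charge: V(r) = sum_s q_s erf(sqrt(a) d)/d,
        with the finite limit 2 q_s sqrt(a/pi) at d = 0.
        """
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 3)
        out = np.zeros(flat.shape[0])
        qs = self.shell_populations
        for c, q, e in zip(self.centers, qs, self.exponents):
            d = np.linalg.norm(flat - c, axis=1)
            sa = np.sqrt(e)
            small = d < 1e-12
            v = np.empty_like(d)
            v[~small] = erf(sa * d[~small]) / d[~small]
            v[small] = 2.0 * sa / np.sqrt(np.pi)
            out += q * v
        return out.reshape(pts.shape[:-1])

    @classmethod
    def from_scaled_proatoms(cls, proatoms) -> "GaussianShellDensity":
        """Flatten a list of ScaledProatom objects into one shell sum."""
        centers, amps, exps = [], [], []
        for sp in proatoms:
            for a, e in zip(sp.base.amplitudes, sp.base.exponents):
                centers.append(sp.center)
                amps.append(sp.coefficient * a)
                exps.append(e)
        return cls(np.array(centers), np.array(amps), np.array(exps))
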