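"""Point-charge quality metrics: dipole error and surface-ESP error.

Atomic partial charges are judged by how well they reproduce (a) the
molecular dipole moment and (b) the electrostatic potential (ESP) on the
2.5-scaled van der Waals surface, where the molecular charge distribution
is essentially exterior and the shell theorem makes point charges a
faithful model for spherical atomic densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .elements import AU_TO_DEBYE, HARTREE_TO_KCALMOL, vdw_radius_bohr
from .grids import MolecularGrid

__all__ = [
    "ChargeSet",
    "ESPSurface",
    "compare_charge_sets",
    "dipole_error",
    "esp_approx",
    "nuclear_charge_center",
    "esp_mae",
    "esp_reference",
    "point_charge_dipole",
    "reference_dipole",
    "sample_vdw_surface",
]


@dataclass(frozen=True)
class ChargeSet:
    """Named set of atomic point charges at nuclear positions (bohr)."""

    scheme_name: str
    charges: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        r = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if r.shape != (q.size, 3):
            raise ValueError("one 3-vector position per charge required")
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "positions", r)


@dataclass(frozen=True)
class ESPSurface:
    """Sample points on the scaled vdW surface with reference ESP values."""

    points: np.ndarray               # (K, 3) bohr
    reference_potential: np.ndarray  # (K,) hartree/e

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        v = np.atleast_1d(np.asarray(self.reference_potential, dtype=float))
        if p.shape[0] != v.size or p.shape[0] < 1:
            raise ValueError("need at least one point with matching potential")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "reference_potential", v)


def nuclear_charge_center(nuclear_charges, positions) -> np.ndarray:
    """Center of nuclear charge — the dipole origin used for charged species."""
    z = np.atleast_1d(np.asarray(nuclear_charges, dtype=float))
    r = np.atleast_2d(np.asarray(positions, dtype=float))
    return (z @ r) / z.sum()


def reference_dipole(rho_mol, grid: MolecularGrid, nuclear_charges,
                     positions, origin=None) -> np.ndarray:
    """Molecular dipole mu = sum_A Z_A R_A - integral r rho(r) dr (a.u.).

    For charged species the dipole is origin-dependent and defaults to the
    center of nuclear charge; pass the same ``origin`` to ``dipole_error``
    when scoring point charges. For neutral molecules the origin is
    irrelevant.
    """
    z = np.atleast_1d(np.asarray(nuclear_charges, dtype=float))
    r_nuc = np.atleast_2d(np.asarray(positions, dtype=float))
    if hasattr(rho_mol, "evaluate"):
        rho = np.asarray(rho_mol.evaluate(grid.points), dtype=float)
    else:
        rho = np.asarray(rho_mol, dtype=float)
    o = nuclear_charge_center(z, r_nuc) if origin is None else np.asarray(origin, float)
    nuclear = z @ (r_nuc - o)
    electronic = (grid.weights * rho) @ (grid.points - o)
    return nuclear - electronic


def point_charge_dipole(cs: ChargeSet, origin=None) -> np.ndarray:
    """Dipole of the point-charge model, sum_A q_A R_A (a.u.)."""
    o = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    return cs.charges @ (cs.positions - o)


def dipole_error(mu_ref, cs: ChargeSet, origin=None) -> float:
    """|mu_ref - sum_A q_A R_A| in Debye; both dipoles in a.u. on input."""
    diff = np.asarray(mu_ref, dtype=float) - point_charge_dipole(cs, origin)
    return float(np.linalg.norm(diff)) * AU_TO_DEBYE


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_vdw_surface(elements, positions, scale: float = 2.5,
                       points_per_atom: int = 170, seed: int | None = None,
                       radii: dict | None = None) -> np.ndarray:
    """Points on the union surface of scale-multiplied vdW spheres.

    Each atom contributes a Fibonacci lattice on its scaled sphere; points
    falling inside any *other* atom's scaled sphere are discarded. A seeded
    random rotation decorrelates the lattice from the molecular axes while
    keeping the sampling deterministic for a given seed.
    """
    if scale <= 0:
        raise ValueError("surface scale must be positive")
    if points_per_atom < 1:
        raise ValueError("points_per_atom must be >= 1")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    rads = np.array([scale * vdw_radius_bohr(el, radii) for el in elements])
    if pos.shape[0] != rads.size:
        raise ValueError("one position per element required")

    base = _fibonacci_sphere(points_per_atom)
    if seed is not None:
        rng = np.random.default_rng(seed)
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        base = base @ rot.T

    kept = []
    for a in range(pos.shape[0]):
        pts = pos[a] + rads[a] * base
        keep = np.ones(pts.shape[0], dtype=bool)
        for b in range(pos.shape[0]):
            if b == a:
                continue
            keep &= np.linalg.norm(pts - pos[b], axis=1) >= rads[b] - 1e-10
        kept.append(pts[keep])
    out = np.concatenate(kept) if kept else np.empty((0, 3))
    if out.shape[0] == 0:
        raise ValueError("no surface points retained; spheres fully overlap")
    return out


def esp_reference(rho_mol, nuclear_charges, positions, points,
                  grid: MolecularGrid | None = None) -> np.ndarray:
    """Reference ESP V(r) = sum_A Z_A/|r-R_A| - electron Coulomb term.

    Analytic (erf closed form) when the density is a Gaussian-shell sum;
    otherwise the electron term is a quadrature Coulomb sum over the grid,
    which is accurate when the evaluation points lie well outside the
    charge distribution (the 2.5-scaled surface regime).
    """
    z = np.atleast_1d(np.asarray(nuclear_charges, dtype=float))
    r_nuc = np.atleast_2d(np.asarray(positions, dtype=float))
    pts = np.atleast_2d(np.asarray(points, dtype=float))

    v = np.zeros(pts.shape[0])
    for za, ra in zip(z, r_nuc):
        d = np.linalg.norm(pts - ra, axis=1)
        if np.any(d < 1e-8):
            raise ValueError("surface point coincides with a nucleus")
        v += za / d

    if hasattr(rho_mol, "coulomb_potential"):
        v -= rho_mol.coulomb_potential(pts)
    else:
        if grid is None:
            raise ValueError("grid required for non-analytic densities")
        if hasattr(rho_mol, "evaluate"):
            rho = np.asarray(rho_mol.evaluate(grid.points), dtype=float)
        else:
            rho = np.asarray(rho_mol, dtype=float)
        wq = grid.weights * rho
        for k in range(pts.shape[0]):
            d = np.linalg.norm(grid.points - pts[k], axis=1)
            v[k] -= float(np.sum(wq / np.maximum(d, 1e-12)))
    return v


def esp_approx(points, cs: ChargeSet) -> np.ndarray:
    """Point-charge ESP sum_A q_A / |r - R_A| at the given points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = np.zeros(pts.shape[0])
    for q, ra in zip(cs.charges, cs.positions):
        d = np.linalg.norm(pts - ra, axis=1)
        if np.any(d < 1e-8):
            raise ValueError("surface point coincides with a nucleus")
        v += q / d
    return v


def esp_mae(surface: ESPSurface, cs: ChargeSet) -> float:
    """Mean absolute ESP error of the point-charge model, kcal/mol per e."""
    err = surface.reference_potential - esp_approx(surface.points, cs)
    return float(np.mean(np.abs(err))) * HARTREE_TO_KCALMOL


def compare_charge_sets(a, b) -> tuple[float, float]:
    """(R^2, slope) of charges in ``a`` regressed on charges in ``b``.

    Accepts single ChargeSets, lists of ChargeSets (pooled across
    molecules), or plain arrays; pairs are matched by position in the
    flattened order. The slope comes from an ordinary least-squares fit of
    a (y) on b (x) with a free intercept.
    """
    def _flatten(x):
        if isinstance(x, ChargeSet):
            return x.charges
        if isinstance(x, (list, tuple)) and x and isinstance(x[0], ChargeSet):
            return np.concatenate([cs.charges for cs in x])
        return np.asarray(x, dtype=float).ravel()

    ya, xb = _flatten(a), _flatten(b)
    if ya.size != xb.size:
        raise ValueError("charge sets must pair one-to-one")
    if ya.size < 3:
        raise ValueError("need at least 3 paired charges")
    fit = stats.linregress(xb, ya)
    return float(fit.rvalue**2), float(fit.slope)
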