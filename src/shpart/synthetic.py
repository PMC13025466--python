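"""Synthetic molecular densities with known ground truth.

Every other module is testable without external data through two density
families built from the model-proatom library:

* exact scaled promolecules, whose true scaling coefficients c*_A are known
  by construction and must be recovered by the partitioners;
* charge-transfer densities, a neutral promolecule perturbed by moving a
  known number of electrons from a donor atom to an acceptor atom via
  atom-centered Gaussian monopoles, which keeps the total electron count
  exact and the ESP analytic while making the density genuinely
  non-promolecular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .density import GaussianShellDensity
from .elements import atomic_number
from .proatoms import RadialProatom, ScaledProatom, build_neutral_proatom

__all__ = [
    "PerturbationTooLargeError",
    "SyntheticSystem",
    "make_charge_transfer_system",
    "make_promolecular_system",
    "random_fixture",
]

DEFAULT_SEED = 20260323


class PerturbationTooLargeError(ValueError):
    """The charge-transfer perturbation would drive the density negative."""


@dataclass(frozen=True)
class SyntheticSystem:
    """A geometry plus an analytic density with known electron count."""

    elements: tuple
    positions: np.ndarray                     # (n, 3) bohr
    density: GaussianShellDensity
    total_electrons: float
    true_coefficients: Optional[np.ndarray]   # None for perturbed densities
    charge_transfer: Optional[dict] = None    # donor/acceptor/amount metadata

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([atomic_number(el) for el in self.elements])

    def proatom_bases(self) -> list[RadialProatom]:
        return [build_neutral_proatom(z) for z in self.atomic_numbers]

    def scaled_proatoms(self) -> list[ScaledProatom]:
        """Neutral (c = 1) proatoms at the nuclear positions."""
        return [
            ScaledProatom(base, pos, 1.0)
            for base, pos in zip(self.proatom_bases(), self.positions)
        ]


def _validate_geometry(elements, positions) -> np.ndarray:
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape != (len(elements), 3):
        raise ValueError("one 3-vector position per element required")
    n = pos.shape[0]
    if n > 1:
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if np.any(d[~np.eye(n, dtype=bool)] < 1e-10):
            raise ValueError("degenerate geometry: coincident atoms")
    return pos


def make_promolecular_system(elements: Sequence[str], positions,
                             coefficients) -> SyntheticSystem:
    """Density that is exactly the scaled promolecule sum_A c*_A rho0_A."""
    pos = _validate_geometry(elements, positions)
    c = np.atleast_1d(np.asarray(coefficients, dtype=float))
    if c.size != len(elements):
        raise ValueError("one coefficient per atom required")
    if np.any(c <= 0):
        raise ValueError("all coefficients must be positive")
    proatoms = [
        ScaledProatom(build_neutral_proatom(atomic_number(el)), p, ci)
        for el, p, ci in zip(elements, pos, c)
    ]
    density = GaussianShellDensity.from_scaled_proatoms(proatoms)
    return SyntheticSystem(
        elements=tuple(elements),
        positions=pos,
        density=density,
        total_electrons=density.total_electrons,
        true_coefficients=c,
    )


def make_charge_transfer_system(
    elements: Sequence[str],
    positions,
    transfer: float,
    width: float = 0.8,
    donor: int = 0,
    acceptor: int = 1,
) -> SyntheticSystem:
    """Neutral promolecule with ``transfer`` electrons moved donor->acceptor.

    The perturbation is a pair of normalized Gaussian monopoles of exponent
    ``width`` (1/bohr^2): -transfer electrons on the donor, +transfer on the
    acceptor, so the total electron count is unchanged exactly. The
    resulting density is checked for nonnegativity at the nuclei and along
    fine radial probes on every internuclear axis; a perturbation that
    drives it negative raises ``PerturbationTooLargeError``.
    """
    pos = _validate_geometry(elements, positions)
    if width <= 0:
        raise ValueError("width must be positive")
    if donor == acceptor:
        raise ValueError("donor and acceptor must differ")
    zs = [atomic_number(el) for el in elements]
    if not 0 <= transfer < zs[donor]:
        raise ValueError("transfer must be nonnegative and below the donor population")

    neutral = make_promolecular_system(elements, pos, np.ones(len(elements)))
    amp = transfer * (width / np.pi) ** 1.5
    centers = np.vstack([neutral.density.centers, pos[donor], pos[acceptor]])
    amps = np.concatenate([neutral.density.amplitudes, [-amp, amp]])
    exps = np.concatenate([neutral.density.exponents, [width, width]])
    density = GaussianShellDensity(centers, amps, exps)

    _check_nonnegative(density, pos)
    return SyntheticSystem(
        elements=tuple(elements),
        positions=pos,
        density=density,
        total_electrons=density.total_electrons,
        true_coefficients=None,
        charge_transfer={"donor": donor, "acceptor": acceptor,
                         "transfer": float(transfer), "width": float(width)},
    )


def _check_nonnegative(density: GaussianShellDensity, positions: np.ndarray):
    """Probe the density at the nuclei and along all internuclear axes."""
    probes = [positions]
    t = np.linspace(0.0, 1.0, 201)[:, None]
    n = positions.shape[0]
    for a in range(n):
        for b in range(a + 1, n):
            seg = positions[a] + t * (positions[b] - positions[a])
            probes.append(seg)
        # radial spokes out of each nucleus catch an over-deep monopole hole
        for direction in np.eye(3):
            probes.append(positions[a] + np.linspace(0, 6, 121)[:, None] * direction)
    values = density.evaluate(np.concatenate(probes))
    if values.min() < 0:
        raise PerturbationTooLargeError(
            f"perturbed density reaches {values.min():.3e} < 0"
        )


def random_fixture(
    seed: int,
    n_atoms_range: tuple[int, int] = (2, 4),
    element_pool: Sequence[str] = ("H", "C", "N", "O", "F"),
    kind: str = "promolecule",
) -> SyntheticSystem:
    """Reproducible random synthetic system.

    Geometry: atoms placed sequentially at 2.2-4.0 bohr from a random
    previously placed atom, rejecting any placement closer than 2.0 bohr to
    an existing atom (so the minimum pair distance is always >= 1.2 bohr).
    Promolecular fixtures draw true coefficients uniformly from [0.7, 1.3];
    charge-transfer fixtures move 0.05-0.25 electrons between the first two
    atoms with a perturbation width drawn from [0.5, 1.2] 1/bohr^2.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
    if kind == "charge_transfer":
        n = max(n, 2)
    elements = [str(rng.choice(element_pool)) for _ in range(n)]

    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            anchor = pos[rng.integers(0, i)]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = anchor + rng.uniform(2.2, 4.0) * direction
            if np.all(np.linalg.norm(pos[:i] - candidate, axis=1) >= 2.0):
                pos[i] = candidate
                break
        else:  # pragma: no cover - rejection sampling practically never exhausts
            raise RuntimeError("could not place atoms with the distance constraint")

    if kind == "promolecule":
        coeff = rng.uniform(0.7, 1.3, size=n)
        return make_promolecular_system(elements, pos, coeff)
    if kind == "charge_transfer":
        transfer = float(rng.uniform(0.05, 0.25))
        width = float(rng.uniform(0.5, 1.2))
        return make_charge_transfer_system(elements, pos, transfer, width)
    raise ValueError(f"unknown fixture kind: {kind!r}")
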