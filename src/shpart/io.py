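"""File formats: XYZ / extended XYZ, Gaussian cube, JSON results, config.

Coordinates are Angstrom in all files (the XYZ convention) and bohr
internally; the conversion constant lives in :mod:`shpart.elements`.
"""

from __future__ import annotations

import ast
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .density import GaussianShellDensity
from .elements import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, atomic_number, symbol

__all__ = [
    "CubeDensity",
    "Geometry",
    "load_config",
    "load_synthetic_system",
    "read_cube",
    "read_xyz",
    "result_to_dict",
    "save_synthetic_system",
    "write_extended_xyz",
    "write_result_json",
]

logger = logging.getLogger(__name__)


class XYZParseError(ValueError):
    pass


@dataclass(frozen=True)
class Geometry:
    elements: tuple
    positions_bohr: np.ndarray
    charge_columns: dict = field(default_factory=dict)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([atomic_number(el) for el in self.elements])


def _parse_properties(spec: str):
    """Parse an extended-XYZ Properties=... triple list into (name, kind, n)."""
    fields = spec.split(":")
    if len(fields) % 3:
        raise XYZParseError(f"malformed Properties string: {spec!r}")
    out = []
    for i in range(0, len(fields), 3):
        out.append((fields[i], fields[i + 1], int(fields[i + 2])))
    return out


def read_xyz(path) -> Geometry:
    """Read plain or extended XYZ (Angstrom). Extra per-atom real columns
    declared in a ``Properties=`` comment line are returned as named charge
    columns."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}:1: expected atom count") from None
    if len(lines) < n_atoms + 2:
        raise XYZParseError(f"{path}: expected {n_atoms} atom rows, file truncated")
    comment = lines[1]

    columns = [("species", "S", 1), ("pos", "R", 3)]
    for token in comment.split():
        if token.startswith("Properties="):
            columns = _parse_properties(token[len("Properties="):])

    elements, rows, extras = [], [], {}
    extra_names = [name for name, kind, n in columns[2:] if kind == "R" and n == 1]
    for name in extra_names:
        extras[name] = []
    for i, line in enumerate(lines[2:2 + n_atoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}:{i}: expected at least 4 columns")
        try:
            z = atomic_number(parts[0])
        except ValueError:
            try:
                z = int(parts[0])
            except ValueError:
                raise XYZParseError(f"{path}:{i}: unknown element {parts[0]!r}") from None
        elements.append(symbol(z))
        try:
            rows.append([float(v) for v in parts[1:4]])
            for j, name in enumerate(extra_names):
                extras[name].append(float(parts[4 + j]))
        except (ValueError, IndexError):
            raise XYZParseError(f"{path}:{i}: malformed numeric field") from None

    positions = np.array(rows) * ANGSTROM_TO_BOHR
    if not np.all(np.isfinite(positions)):
        raise XYZParseError(f"{path}: non-finite coordinates")
    return Geometry(tuple(elements), positions,
                    {k: np.array(v) for k, v in extras.items()})


def write_extended_xyz(path, elements, positions_bohr, charge_columns=None,
                       comment_extra: str = "") -> None:
    """Write extended XYZ with optional per-atom charge columns.

    ``charge_columns`` maps a column name (e.g. ``q_h``, ``q_sh``) to one
    value per atom; columns appear in insertion order after the coordinates.
    """
    charge_columns = charge_columns or {}
    pos = np.atleast_2d(np.asarray(positions_bohr, dtype=float)) * BOHR_TO_ANGSTROM
    props = "species:S:1:pos:R:3"
    for name in charge_columns:
        props += f":{name}:R:1"
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n")
        line = f"Properties={props}"
        if comment_extra:
            line += f" {comment_extra}"
        fh.write(line + "\n")
        for i, el in enumerate(elements):
            row = f"{el:<2s} " + " ".join(f"{x: .10f}" for x in pos[i])
            for name in charge_columns:
                row += f" {charge_columns[name][i]: .10f}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Gaussian cube files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CubeDensity:
    """Volumetric density on a regular (possibly skewed) voxel grid, bohr."""

    origin: np.ndarray
    axes: np.ndarray          # (3, 3): rows are the voxel step vectors
    values: np.ndarray        # (nx, ny, nz), electrons/bohr^3
    atom_numbers: np.ndarray
    atom_positions: np.ndarray

    @property
    def counts(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def integrate(self) -> float:
        """Voxel-sum integral of the density (sanity number)."""
        return float(self.values.sum()) * self.voxel_volume

    def _voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.counts
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        return self.origin + idx @ self.axes

    def dipole_contribution(self) -> np.ndarray:
        """Integral of r * rho over the voxels (a.u.)."""
        w = self.values.ravel() * self.voxel_volume
        return w @ self._voxel_centers()

    def coulomb_potential(self, points) -> np.ndarray:
        """Voxel Coulomb sum; adequate for points outside the density."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        centers = self._voxel_centers()
        w = self.values.ravel() * self.voxel_volume
        out = np.empty(pts.shape[0])
        for k in range(pts.shape[0]):
            d = np.linalg.norm(centers - pts[k], axis=1)
            out[k] = np.sum(w / np.maximum(d, 1e-12))
        return out

    def evaluate(self, points) -> np.ndarray:
        """Trilinear interpolation in fractional voxel coordinates;
        zero outside the box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        frac = (pts - self.origin) @ np.linalg.inv(self.axes)
        grids = [np.arange(n, dtype=float) for n in self.counts]
        interp = RegularGridInterpolator(grids, self.values,
                                         bounds_error=False, fill_value=0.0)
        return interp(frac)


def read_cube(path) -> CubeDensity:
    """Read a Gaussian cube density (bohr units, z-fastest value order).

    A negative atom count on line 3 (the MO-cube convention signalling one
    extra header line after the atoms) is handled and logged. Slightly
    negative voxel values down to -1e-8 are clamped to zero with a logged
    count; anything more negative is rejected.
    """
    with open(path) as fh:
        tokens_by_line = [line.split() for line in fh]
    try:
        natoms = int(tokens_by_line[2][0])
        origin = np.array([float(v) for v in tokens_by_line[2][1:4]])
        counts, axes = [], []
        for i in range(3):
            row = tokens_by_line[3 + i]
            counts.append(int(row[0]))
            axes.append([float(v) for v in row[1:4]])
        extra_header = natoms < 0
        natoms = abs(natoms)
        atom_z, atom_pos = [], []
        for i in range(natoms):
            row = tokens_by_line[6 + i]
            atom_z.append(int(row[0]))
            atom_pos.append([float(v) for v in row[2:5]])
        start = 6 + natoms
        if extra_header:
            logger.info("cube %s: negative atom count convention, skipping "
                        "one dataset-id line", path)
            start += 1
        flat = [float(v) for row in tokens_by_line[start:] for v in row]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed cube header ({exc})") from None

    counts = tuple(counts)
    if any(n < 1 for n in counts):
        raise ValueError(f"{path}: voxel counts must be >= 1")
    expected = counts[0] * counts[1] * counts[2]
    if len(flat) < expected:
        raise ValueError(f"{path}: truncated value block "
                         f"({len(flat)} of {expected} values)")
    values = np.array(flat[:expected]).reshape(counts)
    if values.min() < -1e-8:
        raise ValueError(f"{path}: significantly negative density "
                         f"({values.min():.3e})")
    neg = values < 0
    if np.any(neg):
        logger.warning("cube %s: clamped %d slightly negative voxels",
                       path, int(neg.sum()))
        values = np.where(neg, 0.0, values)
    axes = np.array(axes)
    if np.linalg.det(axes) <= 0:
        raise ValueError(f"{path}: axes do not span a right-handed volume")
    return CubeDensity(origin, axes, values,
                       np.array(atom_z), np.array(atom_pos))


# ---------------------------------------------------------------------------
# Synthetic-system JSON sidecar
# ---------------------------------------------------------------------------

def save_synthetic_system(path, system) -> None:
    """Serialize a SyntheticSystem (shells + ground truth) to JSON."""
    payload = {
        "elements": list(system.elements),
        "positions_bohr": system.positions.tolist(),
        "shells": {
            "centers_bohr": system.density.centers.tolist(),
            "amplitudes": system.density.amplitudes.tolist(),
            "exponents": system.density.exponents.tolist(),
        },
        "total_electrons": system.total_electrons,
        "true_coefficients": (
            None if system.true_coefficients is None
            else system.true_coefficients.tolist()
        ),
        "charge_transfer": system.charge_transfer,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_synthetic_system(path):
    from .synthetic import SyntheticSystem  # local import avoids a cycle

    with open(path) as fh:
        payload = json.load(fh)
    density = GaussianShellDensity(
        np.array(payload["shells"]["centers_bohr"]),
        np.array(payload["shells"]["amplitudes"]),
        np.array(payload["shells"]["exponents"]),
    )
    coeff = payload.get("true_coefficients")
    return SyntheticSystem(
        elements=tuple(payload["elements"]),
        positions=np.array(payload["positions_bohr"]),
        density=density,
        total_electrons=float(payload["total_electrons"]),
        true_coefficients=None if coeff is None else np.array(coeff),
        charge_transfer=payload.get("charge_transfer"),
    )


# ---------------------------------------------------------------------------
# Partition results and configuration
# ---------------------------------------------------------------------------

def result_to_dict(result, elements, positions_bohr) -> dict:
    return {
        "elements": list(elements),
        "coordinates_bohr": np.asarray(positions_bohr).tolist(),
        "coefficients": result.coefficients.tolist(),
        "populations": result.populations.tolist(),
        "charges": result.charges.tolist(),
        "iterations": result.iterations,
        "converged": bool(result.converged),
        "objective": float(result.objective),
        "settings": result.settings,
    }


def write_result_json(path, result, elements, positions_bohr) -> None:
    """Canonical JSON: sorted keys, repr-faithful floats, newline-terminated,
    so identical runs produce byte-identical files."""
    with open(path, "w") as fh:
        json.dump(result_to_dict(result, elements, positions_bohr), fh,
                  indent=1, sort_keys=True)
        fh.write("\n")


def load_config(path: Optional[str] = None) -> dict:
    """Flat key=value config (TOML-style scalars; '#' comments).

    Looks at ``path``, then the SHPART_CONFIG environment variable. Keys use
    dotted names, e.g. ``grid.n_radial = 75``.
    """
    if path is None:
        path = os.environ.get("SHPART_CONFIG")
    if not path:
        return {}
    out = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            value = value.strip()
            try:
                out[key.strip()] = ast.literal_eval(value)
            except (ValueError, SyntaxError):
                out[key.strip()] = value.strip("\"'")
    return out
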