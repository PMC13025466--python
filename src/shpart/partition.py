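"""Stockholder partitioning: Hirshfeld and scaled Hirshfeld (SH).

Stockholder methods divide a molecular electron density rho_mol(r) among
atoms with fuzzy weight functions w_A(r) = proatom_A / promolecule, where
the promolecule is the sum of atom-centered reference densities. The scaled
Hirshfeld variant multiplies each neutral proatom by a coefficient c_A > 0
and determines the coefficients self-consistently by requiring that each
scaled proatom's population c_A * n0_A equals the atomic population

    N_A = integral rho_mol(r) w_A(r) dr.

Two equivalent routes are implemented:

* a fixed-point iteration that alternates population integration with the
  coefficient update c_A = N_A / n0_A, starting from the plain Hirshfeld
  point c_A = 1;
* direct minimization of the extended Kullback-Leibler divergence between
  the molecular and promolecular densities over {c_A}, optionally with an
  explicit electron-count constraint whose Lagrange multiplier vanishes at
  the solution.

The ext-KL objective is strictly convex in {c_A} for linearly independent
proatom profiles, so the solution is unique and independent of the starting
point, and the method is size-consistent: non-interacting fragments give
the same coefficients partitioned jointly or separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize

from .grids import MolecularGrid
from .proatoms import ScaledProatom

__all__ = [
    "DEFAULT_EPSILON",
    "DEFAULT_K_MAX",
    "PROMOLECULE_FLOOR",
    "DivergenceGenerator",
    "EXT_KL",
    "KL",
    "HELLINGER",
    "GENERATORS",
    "PartitionResult",
    "PromoleculeState",
    "StockholderWeights",
    "VariationalSolution",
    "DegeneratePartitionError",
    "atomic_populations",
    "check_generator",
    "f_divergence",
    "get_generator",
    "run_hirshfeld",
    "run_scaled_hirshfeld",
    "solve_variational",
    "stockholder_weights",
    "update_coefficients",
]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-6
DEFAULT_K_MAX = 500
#: Absolute promolecular-density floor: grid points where the promolecule
#: falls below this are excluded from all stockholder integrals. For
#: physical inputs rho_mol is also negligible there, and exclusion keeps
#: sum_A N_A identical to the integral of rho_mol over retained points.
PROMOLECULE_FLOOR = 1e-100


class DegeneratePartitionError(RuntimeError):
    """An atomic population hit zero, so c_A = N_A/n0_A would leave c > 0."""


# ---------------------------------------------------------------------------
# f-divergence generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceGenerator:
    """Convex generator f of an f-divergence, with its derivative.

    Admissible generators for stockholder partitioning satisfy
    f(1) = f'(1) = 0, so the divergence vanishes, with zero slope, when the
    two densities coincide.
    """

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    f_prime: Callable[[np.ndarray], np.ndarray]


EXT_KL = DivergenceGenerator(
    "ext-kl", lambda x: -np.log(x) + x - 1.0, lambda x: 1.0 - 1.0 / x
)
#: Classic KL generator; convex but f'(1) = -1, so it fails the literal
#: admissibility condition f(1) = f'(1) = 0 used here. Kept as a diagnostic.
KL = DivergenceGenerator("kl", lambda x: -np.log(x), lambda x: -1.0 / x)
HELLINGER = DivergenceGenerator(
    "hellinger", lambda x: 0.5 * (x - 1.0) ** 2, lambda x: x - 1.0
)

GENERATORS = {g.name: g for g in (EXT_KL, KL, HELLINGER)}


def get_generator(name: str) -> DivergenceGenerator:
    try:
        return GENERATORS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown divergence generator: {name!r}") from None


def check_generator(gen: DivergenceGenerator, n_samples: int = 400) -> bool:
    """True iff f(1) = f'(1) = 0 (to 1e-12) and f is convex on (0, 20].

    Convexity is checked through second differences on a sampled grid of
    x in [0.05, 20]; values >= -1e-10 pass (numerical-noise allowance).
    """
    if abs(float(gen.f(1.0))) > 1e-12 or abs(float(gen.f_prime(1.0))) > 1e-12:
        return False
    x = np.linspace(0.05, 20.0, n_samples)
    y = gen.f(x)
    return bool(np.all(np.diff(y, 2) >= -1e-10))


def f_divergence(rho_mol, rho_promol, grid: MolecularGrid,
                 gen: DivergenceGenerator | str = EXT_KL) -> float:
    """Integral of rho_mol * f(rho_promol / rho_mol) over the grid.

    Points where rho_mol <= 0 contribute nothing; points where rho_mol > 0
    but rho_promol <= 0 violate the domain of f and are excluded with a
    logged count.
    """
    if isinstance(gen, str):
        gen = get_generator(gen)
    rho = np.asarray(rho_mol, dtype=float)
    rho0 = np.asarray(rho_promol, dtype=float)
    ok = rho > 0
    bad = ok & (rho0 <= 0)
    if np.any(bad):
        logger.warning("f_divergence: excluded %d points with nonpositive "
                       "promolecular density", int(bad.sum()))
        ok &= ~bad
    ratio = rho0[ok] / rho[ok]
    return float(np.sum(grid.weights[ok] * rho[ok] * gen.f(ratio)))


# ---------------------------------------------------------------------------
# Promolecule and stockholder weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoleculeState:
    """Scaled promolecule: rho0_mol(r) = sum_A c_A rho0_A(|r - R_A|)."""

    proatoms: Sequence[ScaledProatom]
    coefficients: np.ndarray

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if c.size != len(self.proatoms):
            raise ValueError("one coefficient per proatom required")
        if np.any(c <= 0):
            raise ValueError("all scaling coefficients must be positive")
        object.__setattr__(self, "coefficients", c)

    def density(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        out = np.zeros(pts.reshape(-1, 3).shape[0])
        for c, sp in zip(self.coefficients, self.proatoms):
            r = np.linalg.norm(pts.reshape(-1, 3) - sp.center, axis=1)
            out += c * sp.base.evaluate(r)
        return out.reshape(pts.shape[:-1])

    @property
    def population(self) -> float:
        n0 = np.array([sp.base.population for sp in self.proatoms])
        return float(self.coefficients @ n0)


class StockholderWeights(NamedTuple):
    weights: np.ndarray   # (n_atoms, n_points); zero at excluded points
    excluded: np.ndarray  # (n_points,) bool


def stockholder_weights(point_densities, coefficients) -> StockholderWeights:
    """Per-atom stockholder weights w_A = c_A p_A / sum_B c_B p_B.

    ``point_densities`` holds the *unscaled* proatom values p_A at each grid
    point, shape (n_atoms, n_points). Points where the scaled promolecular
    density falls below the floor are flagged excluded and get zero weight
    for every atom.
    """
    p = np.atleast_2d(np.asarray(point_densities, dtype=float))
    c = np.atleast_1d(np.asarray(coefficients, dtype=float))
    if np.any(c <= 0):
        raise ValueError("all scaling coefficients must be positive")
    if c.size != p.shape[0]:
        raise ValueError("one coefficient per atom required")
    if np.any(p < 0):
        raise ValueError("proatom point densities must be nonnegative")
    scaled = c[:, None] * p
    promol = scaled.sum(axis=0)
    excluded = promol < PROMOLECULE_FLOOR
    w = np.zeros_like(scaled)
    keep = ~excluded
    w[:, keep] = scaled[:, keep] / promol[keep]
    return StockholderWeights(w, excluded)


def atomic_populations(rho_mol, weights, grid: MolecularGrid) -> np.ndarray:
    """N_A = sum over grid points of grid_weight * rho_mol * w_A."""
    rho = np.asarray(rho_mol, dtype=float)
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if rho.shape != (grid.n_points,) or w.shape[1] != grid.n_points:
        raise ValueError("array lengths do not match the grid")
    if np.any(rho < 0):
        raise ValueError("molecular density values must be nonnegative")
    return w @ (grid.weights * rho)


def update_coefficients(populations, reference_populations) -> np.ndarray:
    """Coefficient update c_A = N_A / n0_A."""
    n = np.atleast_1d(np.asarray(populations, dtype=float))
    n0 = np.atleast_1d(np.asarray(reference_populations, dtype=float))
    if np.any(n0 <= 0):
        raise ValueError("reference populations must be positive")
    if np.any(n < 0):
        raise ValueError("populations must be nonnegative")
    if np.any(n == 0):
        raise DegeneratePartitionError(
            "an atomic population vanished; the updated coefficient would "
            "leave the c_A > 0 domain"
        )
    return n / n0


# ---------------------------------------------------------------------------
# Fixed-point iteration
# ---------------------------------------------------------------------------

@dataclass
class PartitionResult:
    """Converged stockholder partition.

    ``charges`` are q_A = Z_A - N_A in elementary-charge units. ``history``
    records max_A |c_A^{(k+1)} - c_A^{(k)}| per coefficient update;
    ``population_history`` the equivalent max_A |Delta N_A|. ``objective``
    is the final ext-KL divergence between rho_mol and the scaled
    promolecule (dimensionless, electron-weighted).
    """

    atomic_numbers: np.ndarray
    coefficients: np.ndarray
    populations: np.ndarray
    charges: np.ndarray
    iterations: int
    converged: bool
    history: list = field(default_factory=list)
    population_history: list = field(default_factory=list)
    objective: float = np.nan
    objective_history: list = field(default_factory=list)
    n_excluded: int = 0
    settings: dict = field(default_factory=dict)


class _Workspace:
    """Precomputed quantities reused across iterations and solvers."""

    def __init__(self, rho_mol, proatoms, grid: MolecularGrid):
        self.grid = grid
        self.proatoms = list(proatoms)
        self.p = np.stack([
            sp.base.evaluate(np.linalg.norm(grid.points - sp.center, axis=1))
            for sp in self.proatoms
        ])  # (n_atoms, n_points), unscaled
        self.n0 = np.array([sp.base.population for sp in self.proatoms])
        self.z = np.array([sp.base.atomic_number for sp in self.proatoms])
        if hasattr(rho_mol, "evaluate"):
            rho = np.asarray(rho_mol.evaluate(grid.points), dtype=float)
        else:
            rho = np.asarray(rho_mol, dtype=float)
        if rho.shape != (grid.n_points,):
            raise ValueError("density values do not match the grid")
        tiny = rho < 0
        if np.any(tiny):
            if rho.min() < -1e-8:
                raise ValueError("molecular density is significantly negative")
            logger.warning("clamped %d slightly negative density values",
                           int(tiny.sum()))
            rho = np.where(tiny, 0.0, rho)
        self.rho = rho
        self.wrho = grid.weights * rho  # quadrature-weighted density

    def populations(self, c):
        """(N_A, excluded mask) for coefficients c."""
        sw = stockholder_weights(self.p, c)
        n = sw.weights @ self.wrho
        return n, sw.excluded

    def ext_kl(self, c) -> float:
        promol = np.asarray(c) @ self.p
        return f_divergence(self.rho, promol, self.grid, EXT_KL)


def run_scaled_hirshfeld(
    rho_mol,
    proatoms: Sequence[ScaledProatom],
    grid: MolecularGrid,
    epsilon: float = DEFAULT_EPSILON,
    k_max: int = DEFAULT_K_MAX,
    init: Optional[np.ndarray] = None,
    track_objective: bool = False,
) -> PartitionResult:
    """Scaled-Hirshfeld fixed-point iteration.

    Alternates population integration N_A = integral rho_mol w_A dr with the
    coefficient update c_A = N_A / n0_A until max_A |Delta c_A| < epsilon or
    ``k_max`` updates have been made. ``k_max = 0`` performs a single
    population pass at the initial coefficients (the plain Hirshfeld limit).

    ``rho_mol`` may be a density field (with ``.evaluate``) or an array of
    values at the grid points.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    ws = _Workspace(rho_mol, proatoms, grid)
    n_atoms = len(ws.proatoms)
    c = np.ones(n_atoms) if init is None else np.atleast_1d(np.asarray(init, float)).copy()
    if c.size != n_atoms or np.any(c <= 0):
        raise ValueError("init must hold one positive coefficient per atom")

    history: list[float] = []
    pop_history: list[float] = []
    obj_history: list[float] = []
    populations, excluded = ws.populations(c)
    converged = k_max == 0
    iterations = 0
    for k in range(k_max):
        c_new = update_coefficients(populations, ws.n0)
        delta = float(np.max(np.abs(c_new - c)))
        history.append(delta)
        if track_objective:
            obj_history.append(ws.ext_kl(c_new))
        new_pops, excluded = ws.populations(c_new)
        pop_history.append(float(np.max(np.abs(new_pops - populations))))
        # Report the populations that generated c_new, so c_A = N_A/n0_A
        # holds exactly in the result.
        c, iterations = c_new, k + 1
        if delta < epsilon:
            converged = True
            break
        populations = new_pops
    if iterations > 0:
        populations = c * ws.n0
    if not converged:
        logger.warning("fixed-point iteration did not converge in %d updates "
                       "(last |Delta c| = %.3e)", k_max, history[-1])

    return PartitionResult(
        atomic_numbers=ws.z,
        coefficients=c,
        populations=populations,
        charges=ws.z - populations,
        iterations=iterations,
        converged=converged,
        history=history,
        population_history=pop_history,
        objective=ws.ext_kl(c),
        objective_history=obj_history,
        n_excluded=int(excluded.sum()),
        settings={"epsilon": epsilon, "k_max": k_max, "scheme": "sh"},
    )


def run_hirshfeld(rho_mol, proatoms, grid: MolecularGrid) -> PartitionResult:
    """Classic Hirshfeld partitioning: all coefficients fixed at one."""
    result = run_scaled_hirshfeld(rho_mol, proatoms, grid, k_max=0)
    result.settings["scheme"] = "h"
    return result


# ---------------------------------------------------------------------------
# Variational (ext-KL) solver
# ---------------------------------------------------------------------------

class VariationalSolution(NamedTuple):
    coefficients: np.ndarray
    lagrange_multiplier: Optional[float]
    objective: float
    stationarity_residuals: np.ndarray


class OptimizerError(RuntimeError):
    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


def solve_variational(
    rho_mol,
    proatoms: Sequence[ScaledProatom],
    grid: MolecularGrid,
    with_constraint: bool = False,
    tol: float = 1e-12,
) -> VariationalSolution:
    """Minimize the ext-KL divergence over the scaling coefficients.

    Works in log-coefficients u_A = ln c_A, which keeps c_A > 0 without
    bound constraints. The unconstrained problem is solved by Newton
    trust-region minimization with analytic gradient and Hessian. With
    ``with_constraint`` the electron-count condition sum_A c_A n0_A = N_mol
    is enforced through an explicit Lagrange multiplier and the stationarity
    system is solved directly; at the solution the multiplier vanishes,
    which is what reduces the variational problem to the fixed-point one.
    """
    ws = _Workspace(rho_mol, proatoms, grid)
    n_atoms = len(ws.proatoms)
    n_mol = float(np.sum(ws.wrho))

    def raw_populations(c):
        """integral rho * p_A / promol (i.e. N_A / c_A), per atom."""
        promol = c @ ws.p
        keep = promol >= PROMOLECULE_FLOOR
        ratio = np.zeros_like(promol)
        ratio[keep] = ws.wrho[keep] / promol[keep]
        return ws.p @ ratio

    def objective_parts(u):
        c = np.exp(u)
        raw = raw_populations(c)       # N_A / c_A
        n_a = c * raw
        grad_u = c * ws.n0 - n_a       # dF/du_A
        return c, raw, n_a, grad_u

    if with_constraint:
        def equations(x):
            u, lam = x[:n_atoms], x[n_atoms]
            c = np.exp(u)
            raw = raw_populations(c)
            res = np.empty(n_atoms + 1)
            res[:n_atoms] = raw - (1.0 + lam) * ws.n0   # stationarity
            res[n_atoms] = c @ ws.n0 - n_mol            # constraint
            return res

        def jacobian(x):
            u, _lam = x[:n_atoms], x[n_atoms]
            c = np.exp(u)
            promol = c @ ws.p
            keep = promol >= PROMOLECULE_FLOOR
            ratio = ws.p[:, keep] / promol[keep]
            jac_mat = np.zeros((n_atoms + 1, n_atoms + 1))
            jac_mat[:n_atoms, :n_atoms] = -(
                (ratio * ws.wrho[keep]) @ ratio.T
            ) * c[None, :]
            jac_mat[:n_atoms, n_atoms] = -ws.n0
            jac_mat[n_atoms, :n_atoms] = c * ws.n0
            return jac_mat

        sol = optimize.root(equations, np.zeros(n_atoms + 1), jac=jacobian,
                            method="hybr", tol=tol)
        if not sol.success:
            raise OptimizerError(f"constrained solve failed: {sol.message}",
                                 residuals=sol.fun)
        c = np.exp(sol.x[:n_atoms])
        lam = float(sol.x[n_atoms])
        resid = np.abs(sol.fun[:n_atoms]) * c  # back to dL/dc_A scale x c
    else:
        def fun(u):
            c = np.exp(u)
            return ws.ext_kl(c)

        def jac(u):
            return objective_parts(u)[3]

        def hess(u):
            c = np.exp(u)
            promol = c @ ws.p
            keep = promol >= PROMOLECULE_FLOOR
            scaled = c[:, None] * ws.p[:, keep]
            w = scaled / promol[keep]
            n_a = w @ ws.wrho[keep]
            cross = (w * ws.wrho[keep]) @ w.T
            return np.diag(c * ws.n0 - n_a) + cross

        res = optimize.minimize(fun, np.zeros(n_atoms), jac=jac, hess=hess,
                                method="trust-exact",
                                options={"gtol": 1e-13, "max_trust_radius": 2.0})
        u = res.x
        # The objective is strictly convex, so a few Newton steps on the
        # gradient sharpen the minimizer to machine precision when the
        # trust-region loop exits on step size rather than gradient norm.
        for _ in range(25):
            g = jac(u)
            if np.all(np.abs(g) <= 1e-13 * ws.n0):
                break
            u = u - np.linalg.solve(hess(u), g)
        c = np.exp(u)
        lam = None
        resid = np.abs(objective_parts(u)[3])

    if np.any(resid > 1e-8 * ws.n0):
        raise OptimizerError("stationarity residuals exceed 1e-8 * n0",
                             residuals=resid)
    return VariationalSolution(c, lam, ws.ext_kl(c), resid)
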