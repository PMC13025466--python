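# Methods

## The partitioning model

Stockholder ("Hirshfeld") methods divide a molecular electron density
ρ_mol(r) among atoms with weight functions w_A(r) that are everywhere
nonnegative and sum to one, so the atomic densities ρ_A = w_A ρ_mol add
back to ρ_mol exactly. The weights are built from spherically averaged
neutral reference densities ("proatoms") ρ⁰_A placed at the nuclei. In the
scaled-Hirshfeld (SH) variant implemented here, each proatom is multiplied
by a coefficient c_A > 0 and

    w_A(r) = c_A ρ⁰_A(|r − R_A|) / Σ_B c_B ρ⁰_B(|r − R_B|).

The coefficients are fixed by self-consistency between the proatom
populations c_A n⁰_A and the atomic populations N_A = ∫ ρ_mol w_A dr,
giving the update c_A ← N_A / n⁰_A. This fixed point coincides with the
minimizer of the extended Kullback–Leibler (ext-KL) divergence
∫ [ρ_mol ln(ρ_mol/ρ⁰_mol) + ρ⁰_mol − ρ_mol] dr over {c_A}: at the
stationary point of the constrained problem (promolecule and molecule
sharing N_mol electrons) the Lagrange multiplier of the electron-count
constraint is exactly zero, so the constraint is inactive and the
stationarity condition *is* the fixed-point condition. Because the
objective is strictly convex in {c_A} whenever the proatom profiles are
linearly independent, the solution is unique, independent of the starting
point, and size-consistent (the objective of non-interacting fragments is
additive). The package implements both routes and cross-checks them
against each other in the test suite rather than collapsing them into one
code path:

* `run_scaled_hirshfeld` — successive substitution of the population /
  coefficient updates, starting from the plain-Hirshfeld point c_A = 1;
* `solve_variational` — trust-region Newton minimization of the ext-KL
  objective in log-coefficients u_A = ln c_A (which enforces c_A > 0
  without bounds), with analytic gradient c_A n⁰_A − N_A(c) and Hessian,
  polished by Newton steps on the gradient to machine precision; the
  constrained variant solves the full stationarity system with an explicit
  multiplier (Powell hybrid with analytic Jacobian) and reports λ.

Charges are q_A = Z_A − N_A in elementary-charge units, the universal
convention.

## Model proatoms

Built-in proatoms cover Z = 1–36 as sums of three s-type Gaussian shells,
ρ⁰(r) = Σ_j a_j exp(−α_j r²), normalized so the population is exactly Z.
Gaussians were chosen because a spherical Gaussian shell has closed-form
population, dipole and Coulomb potential (an erf expression), which gives
the grid and electrostatics modules analytic oracles. The exponents form a
geometric progression between a core value 2·Z^{4/3} (1/bohr², core
contraction with nuclear charge) and a diffuse value chosen so that
√α_min · (2.5 r_vdW) ≥ 4, i.e. the atomic density is negligible
(≲ 10⁻⁷ e/bohr³) on the 2.5-scaled van der Waals surface — the far-field
property real atomic densities have and on which the surface-ESP metric
relies. Each shell carries Z/3 electrons. These are declared **model
proatoms**: their shapes are not fitted to real atomic densities, and no
claim is made about their fidelity to any element. Users who need
realistic proatoms supply two-column radial tables (r in bohr, ρ in
e/bohr³); these are interpolated with a cubic spline in ln ρ (which
guarantees positivity) and extrapolated beyond the last point as
ρ ∝ exp(−βr) with β taken from the terminal log-slope. Spherical
averaging and multiplet handling for such tables are the user's
responsibility; the package does not guess them.

## Quadrature

All integrals use atom-centered product grids glued with Becke's fuzzy
partition of space (cell functions from the smoothed step
s(μ) = (1 − p_k(μ))/2, p(μ) = 1.5μ − 0.5μ³ iterated k = 3 times — Becke's
original recommendation; optional atomic-size adjustment of the cell
boundaries is off by default). Radial: Gauss–Chebyshev (second kind) nodes
under the rational map r = R_m(1+x)/(1−x), with per-element midpoint R_m
equal to half a Bragg-Slater-like covalent radius (fallback 1 bohr).
Angular: Gauss–Legendre in cos θ × uniform trapezoid in φ; order L means
(L+1) × (2L+2) nodes and integrates spherical harmonics up to degree L
exactly. This self-contained product rule replaces tabulated Lebedev
grids; it is somewhat less node-efficient but exact for band-limited
integrands and entirely adequate for smooth Gaussian densities. No
pruning is applied — pruning is an efficiency device, not a correctness
requirement at the problem sizes this package targets (a few atoms).

Defaults: `n_radial = 75`, `angular_order = 17`, `becke_iterations = 3`
(config keys `grid.n_radial`, `grid.angular_order`,
`grid.becke_iterations`). At these settings `grid_selfcheck` — the maximum
absolute deviation between quadrature and closed-form proatom populations
— stays below 5×10⁻⁴ e on multi-center systems (typically ~10⁻⁶ e), the
accuracy target adopted for production grids, and recovery of known
promolecule coefficients is grid-limited at ~10⁻⁶.

## Numerical choices

* Fixed-point stopping rule: max_A |Δc_A| < ε, default ε = 10⁻⁶, at most
  k_max = 500 updates; convergence is also tracked on populations
  (max_A |ΔN_A|), which is an equivalent criterion. Non-convergence
  returns a flagged result with a logged warning rather than raising.
* Promolecule floor τ = 10⁻¹⁰⁰ e/bohr³ (absolute): grid points where the
  promolecule falls below τ are excluded from every stockholder integral.
  For physical inputs ρ_mol is also negligible there, and exclusion keeps
  Σ_A N_A identical to the integral of ρ_mol over retained points, so
  conservation holds to 10⁻¹² relative at every iteration.
* The reported result satisfies c_A = N_A/n⁰_A exactly (populations are
  the ones that generated the final coefficients).
* `k_max = 0` performs a single population pass at the initial
  coefficients; `run_hirshfeld` is exactly this limit, so plain Hirshfeld
  and SH share one code path bit-for-bit.
* The ext-KL objective value is recorded per run (and optionally per
  iteration); nothing is asserted about its monotonicity along the
  fixed-point trajectory.
* Degenerate inputs: coincident nuclei are rejected at grid construction
  (where they would also make the Becke partition singular and the
  proatom profiles linearly dependent); a vanishing atomic population
  raises a degenerate-partition error, since the updated coefficient
  would leave the c_A > 0 domain. No tie-breaking is needed anywhere —
  strict convexity makes the solution unique.
* f-divergence generators: admissibility is the literal contract
  f(1) = f′(1) = 0 plus convexity (checked by second differences on
  x ∈ [0.05, 20], tolerance −10⁻¹⁰). The classic KL generator
  f(x) = −ln x is convex but has f′(1) = −1, so `check_generator`
  rejects it under this contract even though the KL divergence appears in
  the older stockholder literature in a normalized form; it and the
  squared-Hellinger generator ½(x−1)² are shipped as diagnostics only.
  The ext-KL generator −ln x + x − 1 is the one the optimizer uses,
  because molecule and promolecule need not be normalized to each other.

## Electrostatic quality metrics

* Dipole error: ‖μ_ref − Σ_A q_A R_A‖ converted at 1 a.u. =
  2.5417464519 D. μ_ref = Σ_A Z_A R_A − ∫ r ρ_mol dr is evaluated on the
  molecular grid. For charged species the dipole is origin-dependent; the
  center of nuclear charge is the default origin and the same origin must
  be used on both sides of the comparison (for neutral molecules the
  choice is irrelevant).
* Surface ESP: points are sampled on each atom's 2.5-scaled van der Waals
  sphere from a Fibonacci lattice (deterministically rotated by a seeded
  random rotation), discarding points inside any other atom's scaled
  sphere; default 170 points/atom before exclusion. The metric is the
  plain (equal-weight) mean of |V_ref − Σ_A q_A/|r−R_A|| over retained
  points, converted at 1 hartree = 627.5094740631 kcal/mol; no area
  weighting is applied. Radii are a Bondi-style table (H 1.20 Å, C 1.70 Å,
  N 1.55 Å, O 1.52 Å, …) with a per-call override. V_ref is analytic
  (erf closed form) for Gaussian-shell densities and a voxel/quadrature
  Coulomb sum for gridded densities — accurate there because the surface
  points lie far outside the charge distribution.
* Charge-set comparison: squared Pearson correlation and free-intercept
  OLS slope of one scheme's charges against another's, pooled across
  molecules.

The shell theorem is what makes these metrics sharp oracles: for a density
that is exactly a superposition of spherical atomic terms, the SH point
charges reproduce the dipole and the exterior ESP essentially exactly
(residuals are pure grid/convergence noise, < 10⁻³ D and < 10⁻³ kcal/mol
at default settings).

## Synthetic data: what it emulates and what it does not

The generator produces two families with exact ground truth:

* **Promolecular systems** — densities that are exactly Σ_A c*_A ρ⁰_A with
  known c*_A ∈ [0.7, 1.3] (the range typical of neutral organic
  molecules). These probe recovery: the partitioner must return c*.
* **Charge-transfer systems** — a neutral promolecule plus a pair of
  normalized Gaussian monopoles (−t on a donor atom, +t on an acceptor,
  t ∈ [0.05, 0.25] e, width 0.5–1.2 bohr⁻²) so the electron count is
  conserved exactly while the density is genuinely non-promolecular.
  Nonnegativity is verified on probes at the nuclei, along every
  internuclear axis and along radial spokes; an over-deep perturbation is
  rejected. Monopoles sit on atoms rather than bond midpoints so the
  density remains a sum of atom-centered spherical terms with analytic
  ESP; bond-centered deformations are an extension point.

Random fixtures place 2–6 atoms (pool H, C, N, O, F) sequentially at
2.2–4.0 bohr from a previously placed atom with a 2.0 bohr minimum
separation — bond-length-scale geometries without any valence logic. All
randomness flows through explicit integer seeds (package default
20260323).

What passing tests on these data do **not** show: fidelity to real
molecular densities. Real densities have deformation features (lone
pairs, π systems, bond charge accumulation) that are neither spherical
nor atom-centered, and real proatoms are not three-Gaussian models. The
synthetic families validate the mathematics of the method — convergence,
uniqueness, equivalence of the two formulations, conservation, size
consistency, and the electrostatics in the spherical limit — not its
chemical accuracy on any particular molecule.

## Known limitations

* Built-in proatoms are unvalidated models; quantitative charges for real
  systems require user-supplied proatom tables and a real density (cube).
* Charged-proatom reference sets (as used by iterative-Hirshfeld-type
  schemes) are out of scope; only neutral references are scaled.
* The cube reader interpolates trilinearly; very coarse cubes limit both
  partitioning and ESP accuracy, and the voxel Coulomb sum is only valid
  for evaluation points outside the boxed density.
* The angular product grid is less economical than Lebedev quadrature;
  for molecules beyond ~10 atoms the grids get large (the intended use is
  desk-scale systems).
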