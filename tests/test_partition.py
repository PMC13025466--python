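import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shpart import (
    EXT_KL,
    HELLINGER,
    KL,
    DivergenceGenerator,
    atomic_populations,
    build_molecular_grid,
    check_generator,
    f_divergence,
    get_generator,
    make_promolecular_system,
    run_hirshfeld,
    run_scaled_hirshfeld,
    solve_variational,
    stockholder_weights,
    update_coefficients,
)
from shpart.partition import DegeneratePartitionError
from shpart.proatoms import ScaledProatom, build_neutral_proatom
from shpart.synthetic import random_fixture

SEED = 20260323


def partition_inputs(system, n_radial=50, angular_order=11):
    grid = build_molecular_grid(system.positions, system.atomic_numbers,
                                n_radial=n_radial, angular_order=angular_order)
    return grid, system.scaled_proatoms()


class TestStockholderWeights:
    def test_symmetric_point_equal_split(self):
        sw = stockholder_weights([[0.3], [0.3]], [1.0, 1.0])
        np.testing.assert_allclose(sw.weights, [[0.5], [0.5]])
        assert not sw.excluded[0]

    def test_coefficient_ratio(self):
        sw = stockholder_weights([[0.3], [0.3]], [2.0, 1.0])
        np.testing.assert_allclose(sw.weights, [[2 / 3], [1 / 3]])

    def test_vanishing_promolecule_point_excluded(self):
        sw = stockholder_weights([[0.0, 0.2], [0.0, 0.2]], [1.0, 1.0])
        assert sw.excluded[0] and not sw.excluded[1]
        np.testing.assert_array_equal(sw.weights[:, 0], 0.0)

    def test_invalid_coefficient_rejected(self):
        with pytest.raises(ValueError):
            stockholder_weights([[0.1], [0.1]], [1.0, -0.5])

    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=5),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_of_unity_property(self, coeffs, seed):
        """Weights are nonnegative and sum to one wherever the promolecule
        survives the floor, for arbitrary positive coefficients."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.0, 1.0, size=(len(coeffs), 40))
        sw = stockholder_weights(p, coeffs)
        keep = ~sw.excluded
        assert np.all(sw.weights >= 0)
        np.testing.assert_allclose(sw.weights[:, keep].sum(axis=0), 1.0,
                                   atol=1e-12)


class TestAtomicPopulations:
    def test_symmetric_homonuclear_pair(self):
        sys_ = make_promolecular_system(
            ["N", "N"], [[0, 0, -1.05], [0, 0, 1.05]], [1.0, 1.0])
        grid, pro = partition_inputs(sys_)
        p = np.stack([sp.evaluate(grid.points) for sp in pro])
        sw = stockholder_weights(p, [1.0, 1.0])
        pops = atomic_populations(sys_.density.evaluate(grid.points),
                                  sw.weights, grid)
        assert pops[0] == pytest.approx(pops[1], rel=1e-10)

    def test_single_atom_gets_everything(self):
        sys_ = make_promolecular_system(["C"], [[0, 0, 0]], [1.2])
        grid, pro = partition_inputs(sys_)
        rho = sys_.density.evaluate(grid.points)
        p = np.stack([pro[0].evaluate(grid.points)])
        sw = stockholder_weights(p, [1.0])
        pops = atomic_populations(rho, sw.weights, grid)
        assert pops[0] == pytest.approx(grid.integrate(rho), rel=1e-14)

    def test_far_separated_pair_recovers_fragment_populations(self):
        sys_ = make_promolecular_system(
            ["H", "H"], [[0, 0, 0], [0, 0, 20.0]], [0.9, 1.1])
        grid, pro = partition_inputs(sys_)
        p = np.stack([sp.evaluate(grid.points) for sp in pro])
        sw = stockholder_weights(p, [1.0, 1.0])
        pops = atomic_populations(sys_.density.evaluate(grid.points),
                                  sw.weights, grid)
        np.testing.assert_allclose(pops, [0.9, 1.1], atol=5e-4)

    def test_shape_mismatch_rejected(self):
        sys_ = make_promolecular_system(["H"], [[0, 0, 0]], [1.0])
        grid, _ = partition_inputs(sys_)
        with pytest.raises(ValueError):
            atomic_populations(np.ones(3), np.ones((1, 3)), grid)


class TestUpdateCoefficients:
    @pytest.mark.parametrize("n, n0, expected", [
        ([6.2], [6.0], [31 / 30]),
        ([6.0], [6.0], [1.0]),
        ([0.9, 7.1], [1.0, 8.0], [0.9, 0.8875]),
    ])
    def test_arithmetic(self, n, n0, expected):
        np.testing.assert_allclose(update_coefficients(n, n0), expected,
                                   rtol=1e-15)

    def test_zero_population_is_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            update_coefficients([0.0, 5.0], [1.0, 8.0])


class TestFixedPoint:
    def test_single_atom_scaled_density_one_update(self):
        sys_ = make_promolecular_system(["O"], [[0, 0, 0]], [1.3])
        grid, pro = partition_inputs(sys_)
        res = run_scaled_hirshfeld(sys_.density, pro, grid, epsilon=1e-10)
        assert res.converged
        assert res.coefficients[0] == pytest.approx(1.3, abs=1e-6)
        # weight is identically 1, so the first update already lands on 1.3
        assert res.history[0] == pytest.approx(0.3, abs=1e-5)

    def test_exact_promolecule_recovery(self, hf_system, hf_grid):
        res = run_scaled_hirshfeld(hf_system.density,
                                   hf_system.scaled_proatoms(), hf_grid,
                                   epsilon=1e-9)
        assert res.converged
        np.testing.assert_allclose(res.coefficients,
                                   hf_system.true_coefficients, atol=1e-5)

    def test_neutral_promolecule_is_a_fixed_point(self, water_like_system):
        sys_ = make_promolecular_system(
            water_like_system.elements, water_like_system.positions,
            np.ones(3))
        grid, pro = partition_inputs(sys_)
        res = run_scaled_hirshfeld(sys_.density, pro, grid, epsilon=1e-5)
        assert res.converged and res.iterations == 1
        assert res.history[0] < 1e-5

    def test_conservation_every_iteration(self, hf_system, hf_grid):
        """sum_A N_A equals the grid integral of rho at each iteration."""
        rho = hf_system.density.evaluate(hf_grid.points)
        total = hf_grid.integrate(rho)
        pro = hf_system.scaled_proatoms()
        p = np.stack([sp.evaluate(hf_grid.points) for sp in pro])
        c = np.ones(2)
        for _ in range(5):
            sw = stockholder_weights(p, c)
            pops = atomic_populations(rho, sw.weights, hf_grid)
            assert pops.sum() == pytest.approx(total, rel=1e-12)
            c = update_coefficients(pops, [sp.base.population for sp in pro])

    def test_result_invariants(self, hf_system, hf_grid):
        res = run_scaled_hirshfeld(hf_system.density,
                                   hf_system.scaled_proatoms(), hf_grid,
                                   epsilon=1e-8)
        n0 = np.array([sp.base.population
                       for sp in hf_system.scaled_proatoms()])
        np.testing.assert_allclose(res.coefficients, res.populations / n0,
                                   rtol=1e-13)
        np.testing.assert_allclose(res.charges,
                                   res.atomic_numbers - res.populations,
                                   rtol=1e-13)
        assert res.history[-1] < 1e-8
        assert res.objective >= -1e-12

    def test_nonconvergence_reported_not_raised(self, hf_system, hf_grid):
        res = run_scaled_hirshfeld(hf_system.density,
                                   hf_system.scaled_proatoms(), hf_grid,
                                   epsilon=1e-14, k_max=2)
        assert not res.converged
        assert res.iterations == 2

    def test_uniqueness_across_initial_guesses(self, hf_system, hf_grid):
        rng = np.random.default_rng(SEED)
        eps = 1e-9
        sols = [
            run_scaled_hirshfeld(
                hf_system.density, hf_system.scaled_proatoms(), hf_grid,
                epsilon=eps, init=rng.uniform(0.2, 4.0, size=2)
            ).coefficients
            for _ in range(5)
        ]
        assert np.max(np.ptp(np.array(sols), axis=0)) < 10 * eps

    def test_permutation_symmetry(self):
        sys_ = make_promolecular_system(
            ["H", "O", "N"],
            [[0, 0, 0], [0, 0, 2.0], [2.1, 0, 0.5]], [0.8, 1.1, 1.2])
        perm = [2, 0, 1]
        sys_p = make_promolecular_system(
            [sys_.elements[i] for i in perm], sys_.positions[perm],
            sys_.true_coefficients[perm])
        r1 = run_scaled_hirshfeld(sys_.density, sys_.scaled_proatoms(),
                                  partition_inputs(sys_)[0], epsilon=1e-9)
        r2 = run_scaled_hirshfeld(sys_p.density, sys_p.scaled_proatoms(),
                                  partition_inputs(sys_p)[0], epsilon=1e-9)
        np.testing.assert_allclose(r2.coefficients, r1.coefficients[perm],
                                   atol=1e-8)

    def test_homonuclear_symmetric_coefficients(self):
        sys_ = make_promolecular_system(
            ["O", "O"], [[0, 0, -1.15], [0, 0, 1.15]], [1.07, 1.07])
        grid, pro = partition_inputs(sys_)
        res = run_scaled_hirshfeld(sys_.density, pro, grid, epsilon=1e-10)
        assert abs(res.coefficients[0] - res.coefficients[1]) < 1e-10


class TestHirshfeldLimit:
    def test_hirshfeld_equals_kmax_zero(self, hf_system, hf_grid):
        pro = hf_system.scaled_proatoms()
        h = run_hirshfeld(hf_system.density, pro, hf_grid)
        sh0 = run_scaled_hirshfeld(hf_system.density, pro, hf_grid, k_max=0)
        np.testing.assert_array_equal(h.coefficients, sh0.coefficients)
        np.testing.assert_array_equal(h.populations, sh0.populations)
        np.testing.assert_array_equal(h.charges, sh0.charges)

    def test_neutral_promolecule_gives_zero_charges(self, water_like_system):
        sys_ = make_promolecular_system(
            water_like_system.elements, water_like_system.positions,
            np.ones(3))
        grid, pro = partition_inputs(sys_)
        res = run_hirshfeld(sys_.density, pro, grid)
        np.testing.assert_allclose(res.charges, 0.0, atol=5e-4)
        np.testing.assert_array_equal(res.coefficients, 1.0)

    def test_symmetric_diatomic_equal_charges(self):
        sys_ = make_promolecular_system(
            ["C", "C"], [[0, 0, -1.2], [0, 0, 1.2]], [1.0, 1.0])
        grid, pro = partition_inputs(sys_)
        res = run_hirshfeld(sys_.density, pro, grid)
        assert res.charges[0] == pytest.approx(res.charges[1], abs=1e-10)


class TestDivergences:
    def test_identical_densities_vanish(self, hf_system, hf_grid):
        rho = hf_system.density.evaluate(hf_grid.points)
        for gen in (EXT_KL, HELLINGER):
            assert abs(f_divergence(rho, rho, hf_grid, gen)) < 1e-12

    def test_ext_kl_admissible_at_one(self):
        assert EXT_KL.f(1.0) == 0.0
        assert EXT_KL.f_prime(1.0) == 0.0

    def test_hellinger_closed_form(self):
        assert HELLINGER.f(3.0) == pytest.approx(2.0)

    def test_generator_lookup(self):
        assert get_generator("ext-kl") is EXT_KL
        with pytest.raises(ValueError):
            get_generator("tsallis")

    @pytest.mark.parametrize("gen, admissible", [
        (EXT_KL, True),
        (HELLINGER, True),
        (KL, False),  # f'(1) = -1
        (DivergenceGenerator("linear", lambda x: x - 1.0,
                             lambda x: np.ones_like(np.asarray(x, float))),
         False),  # f'(1) = 1
    ])
    def test_check_generator(self, gen, admissible):
        assert check_generator(gen) is admissible

    def test_divergence_positive_for_distinct_densities(self, hf_system,
                                                        hf_grid):
        rho = hf_system.density.evaluate(hf_grid.points)
        promol = 1.15 * rho
        assert f_divergence(rho, promol, hf_grid, EXT_KL) > 0


class TestVariational:
    def test_exact_promolecule_recovery(self, hf_system, hf_grid):
        sol = solve_variational(hf_system.density,
                                hf_system.scaled_proatoms(), hf_grid)
        np.testing.assert_allclose(sol.coefficients,
                                   hf_system.true_coefficients, atol=1e-5)
        assert sol.lagrange_multiplier is None

    def test_matches_fixed_point(self):
        for seed in (11, 12, 13):
            s = random_fixture(seed, n_atoms_range=(2, 4))
            grid, pro = partition_inputs(s)
            fp = run_scaled_hirshfeld(s.density, pro, grid, epsilon=1e-9)
            var = solve_variational(s.density, pro, grid)
            np.testing.assert_allclose(var.coefficients, fp.coefficients,
                                       atol=1e-6)

    def test_constrained_multiplier_vanishes(self, hf_system, hf_grid):
        sol = solve_variational(hf_system.density,
                                hf_system.scaled_proatoms(), hf_grid,
                                with_constraint=True)
        assert abs(sol.lagrange_multiplier) <= 1e-6
        np.testing.assert_allclose(sol.coefficients,
                                   hf_system.true_coefficients, atol=1e-5)

    def test_stationarity_residuals_small(self, hf_system, hf_grid):
        n0 = np.array([sp.base.population
                       for sp in hf_system.scaled_proatoms()])
        sol = solve_variational(hf_system.density,
                                hf_system.scaled_proatoms(), hf_grid)
        assert np.all(sol.stationarity_residuals <= 1e-8 * n0)


class TestSizeConsistency:
    def test_far_fragments_partition_independently(self):
        a = make_promolecular_system(
            ["H", "O"], [[0, 0, 0], [0, 0, 1.8]], [0.9, 1.05])
        b = make_promolecular_system(
            ["C", "N"], [[30, 0, 0], [30, 0, 2.2]], [1.1, 0.95])
        joint = make_promolecular_system(
            ["H", "O", "C", "N"],
            np.vstack([a.positions, b.positions]),
            np.concatenate([a.true_coefficients, b.true_coefficients]))
        rj = run_scaled_hirshfeld(joint.density, joint.scaled_proatoms(),
                                  partition_inputs(joint)[0], epsilon=1e-9)
        ra = run_scaled_hirshfeld(a.density, a.scaled_proatoms(),
                                  partition_inputs(a)[0], epsilon=1e-9)
        rb = run_scaled_hirshfeld(b.density, b.scaled_proatoms(),
                                  partition_inputs(b)[0], epsilon=1e-9)
        sep = np.concatenate([ra.coefficients, rb.coefficients])
        np.testing.assert_allclose(rj.coefficients, sep, atol=1e-5)
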