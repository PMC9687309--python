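"""Optimizer building blocks: objective, constraint, sensitivities, filters,
MMA updates, and small end-to-end reconstructions."""

import numpy as np
import pytest

from trabtopo import fem
from trabtopo.localize import estimate_local_loads
from trabtopo.materials import MaterialParams, simp_modulus
from trabtopo.mma import MMAOptions, MMAState, mma_update
from trabtopo.reconstruct import (OptimizerParams, constraint_value,
                                  continuum_deviation, density_filter,
                                  filter_backprop, objective,
                                  run_reconstruction, sensitivities)
from trabtopo.refine import ROISpec

from conftest import plate_model


def toy_problem(rho, seed=50):
    """Small all-design plate with a fixed off-centre load."""
    _, m = plate_model(rho)
    f = np.zeros(m.n_dofs)
    nr, nc = rho.shape
    f[2 * m.node_id[nr, nc // 2] + 1] = -100.0
    f[2 * m.node_id[nr, nc // 4]] = 30.0
    return m, f


class TestObjective:
    def test_single_case_equals_strain_energy(self):
        rng = np.random.default_rng(51)
        rho = 0.3 + 0.6 * rng.random((5, 5))
        m, f = toy_problem(rho)
        u = fem.solve(m, f)
        _, total = fem.strain_energy(m, u)
        assert objective(m, [f], [1.0]) == pytest.approx(total, rel=1e-9)

    def test_weighted_sum_linearity(self):
        rng = np.random.default_rng(52)
        rho = 0.3 + 0.6 * rng.random((5, 5))
        m, f = toy_problem(rho)
        f2 = np.roll(f, 2)
        f3 = 0.5 * f
        weights = [0.6, 0.2, 0.2]
        combined = objective(m, [f, f2, f3], weights)
        singles = [objective(m, [g], [1.0]) for g in (f, f2, f3)]
        assert combined == pytest.approx(
            sum(w * s for w, s in zip(weights, singles)), rel=1e-9)

    def test_simp_density_scaling(self):
        # doubling a uniform density divides compliance by 8 (gamma = 3)
        m1, f = toy_problem(np.full((4, 4), 0.4))
        m2, _ = toy_problem(np.full((4, 4), 0.8))
        c1 = objective(m1, [f], [1.0])
        c2 = objective(m2, [f], [1.0])
        assert c1 / c2 == pytest.approx(8.0, rel=1e-9)


class TestConstraintValue:
    def test_zero_at_parent(self):
        rho = np.full(10, 0.4)
        assert constraint_value(rho, rho) == 0.0

    def test_uniform_deviation(self):
        assert constraint_value(np.full(7, 0.5), np.full(7, 0.3)) == pytest.approx(0.04)

    def test_hand_computed_example(self):
        rho0 = np.array([0.5, 0.5, 0.5, 0.5])
        rho = rho0 + np.array([0.1, 0.0, -0.1, 0.2])
        assert constraint_value(rho, rho0) == pytest.approx(0.015)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            constraint_value(np.ones(3), np.ones(4))


class TestSensitivities:
    def test_compliance_gradient_nonpositive_and_fd(self):
        rng = np.random.default_rng(53)
        rho = 0.3 + 0.5 * rng.random((4, 4))
        params = MaterialParams()
        m, f = toy_problem(rho)
        us = [fem.solve(m, f, K=fem.assemble(m))]
        dF, dG = sensitivities(rho.ravel(), rho.ravel(), m, us, [1.0], params)
        assert np.all(dF <= 0)
        assert np.allclose(dG, 0.0)

        # central finite differences at 10 random elements
        h = 1e-6
        idx = rng.choice(rho.size, size=10, replace=False)
        for i in idx:
            for sgn, store in ((+1, "hi"), (-1, "lo")):
                r = rho.ravel().copy()
                r[i] += sgn * h
                mm, _ = toy_problem(r.reshape(rho.shape))
                val = objective(mm, [f], [1.0])
                if sgn > 0:
                    hi = val
                else:
                    lo = val
            fd = (hi - lo) / (2 * h)
            assert fd == pytest.approx(dF[i], rel=1e-3)

    def test_constraint_gradient(self):
        rho0 = np.linspace(0.2, 0.8, 9)
        rho = rho0 + 0.05
        m, _ = toy_problem(np.full((3, 3), 0.5))
        _, dG = sensitivities(rho, rho0, m, [np.zeros(m.n_dofs)], [1.0])
        assert np.allclose(dG, 2 * 0.05 / 9)


class TestDensityFilter:
    def test_radius_zero_identity(self):
        rng = np.random.default_rng(54)
        x = rng.random((8, 8))
        assert np.array_equal(density_filter(x, 0.0), x)

    def test_constant_field_unchanged(self):
        x = np.full((10, 10), 0.37)
        assert np.allclose(density_filter(x, 2.5), x)

    def test_interior_spike_mass_preserved(self):
        x = np.zeros((15, 15))
        x[7, 7] = 1.0
        y = density_filter(x, 1.5)
        assert y[7, 7] < 1.0
        assert y[7, 8] > 0
        assert y.sum() == pytest.approx(1.0, abs=1e-6)
        assert y.mean() == pytest.approx(x.mean(), abs=1e-6)

    def test_backprop_is_adjoint(self):
        rng = np.random.default_rng(55)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        lhs = float((density_filter(a, 1.5) * b).sum())
        rhs = float((a * filter_backprop(b, 1.5)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestContinuumDeviation:
    def test_zero_at_parent(self):
        rho0 = np.random.default_rng(56).random((12, 12))
        g, dG = continuum_deviation(rho0, rho0, 4)
        assert g == 0.0
        assert np.all(dG == 0.0)

    def test_subpixel_rearrangement_nearly_free(self):
        # moving mass within a parent pixel barely changes g; a uniform
        # shift of the whole field costs the full squared offset
        rho0 = np.full((12, 12), 0.5)
        polarized = np.kron(np.ones((3, 3)), np.tile([[1.0, 0.0]], (4, 2)))
        g_polar, _ = continuum_deviation(polarized, rho0, 4)
        g_shift, _ = continuum_deviation(rho0 + 0.2, rho0, 4)
        assert g_shift == pytest.approx(0.04, rel=1e-9)
        assert g_polar < 0.3 * g_shift

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(57)
        rho0 = rng.random((8, 8))
        rho = np.clip(rho0 + 0.1 * rng.standard_normal((8, 8)), 0, 1)
        g, dG = continuum_deviation(rho, rho0, 4)
        h = 1e-7
        for k in rng.choice(64, 6, replace=False):
            r = rho.copy().ravel()
            r[k] += h
            g_hi, _ = continuum_deviation(r.reshape(8, 8), rho0, 4)
            r[k] -= 2 * h
            g_lo, _ = continuum_deviation(r.reshape(8, 8), rho0, 4)
            assert (g_hi - g_lo) / (2 * h) == pytest.approx(dG[k], rel=1e-5, abs=1e-12)


class TestMMA:
    def test_stationary_point_unchanged(self):
        x = np.full(5, 0.5)
        state = MMAState()
        xn = mma_update(x, np.zeros(5), 0.0, np.zeros(5), 0.01,
                        np.full(5, 0.01), np.ones(5), state)
        assert np.allclose(xn, x, atol=1e-12)

    def test_descent_direction_with_slack_constraint(self):
        x = np.full(6, 0.5)
        state = MMAState()
        xn = mma_update(x, -np.ones(6), 0.0, np.zeros(6), 1.0,
                        np.full(6, 0.01), np.ones(6), state)
        assert np.all(xn >= x)

    def test_respects_move_limit_and_bounds(self):
        x = np.array([0.02, 0.5, 0.99])
        state = MMAState()
        xn = mma_update(x, np.array([-100.0, -100.0, -100.0]), 0.0,
                        np.zeros(3), 1.0, np.full(3, 0.01), np.ones(3), state,
                        MMAOptions(move_limit=0.1))
        assert np.all(xn <= np.minimum(1.0, x + 0.1 * 0.99) + 1e-12)
        assert np.all(xn >= 0.01)

    def test_two_variable_toy_matches_grid_search(self):
        # min c1/x1 + c2/x2  s.t. mean((x - x0)^2) <= eps, x in [0.01, 1]
        c = np.array([1.0, 2.0])
        x0 = np.array([0.4, 0.4])
        eps = 0.01

        def fval(x):
            return float(np.sum(c / x))

        def gval(x):
            return float(np.mean((x - x0) ** 2))

        xs = np.round(np.arange(0.01, 1.0001, 0.01), 10)
        best, best_f = None, np.inf
        for a in xs:
            for b in xs:
                x = np.array([a, b])
                if gval(x) <= eps and fval(x) < best_f:
                    best, best_f = x, fval(x)

        x = x0.copy()
        state = MMAState()
        for _ in range(200):
            df = -c / x**2
            dg = 2 * (x - x0) / 2
            xn = mma_update(x, df, gval(x), dg, eps,
                            np.full(2, 0.01), np.ones(2), state)
            if np.abs(xn - x).max() < 1e-7:
                x = xn
                break
            x = xn
        assert gval(x) <= eps + 1e-6
        assert np.abs(x - best).max() <= 0.01 + 1e-9
        assert fval(x) <= best_f + 0.05


@pytest.fixture(scope="module")
def tiny_setup():
    """4x4 LR plate, localized loads for a centred 2x2 ROI."""
    rng = np.random.default_rng(58)
    values = np.round(0.3 + 0.5 * rng.random((4, 4)), 6)
    img, m = plate_model(values)
    f = np.zeros(m.n_dofs)
    for j in range(5):
        f[2 * m.node_id[4, j] + 1] = -40.0
    roi = ROISpec(1, 1, 2, 2)
    lls = estimate_local_loads(m, [f], roi)
    return img, m, f, roi, lls


class TestRunReconstruction:
    def test_localized_run_contract(self, tiny_setup):
        img, m, f, roi, lls = tiny_setup
        opt = OptimizerParams(max_iters=60, change_tol=0.005)
        res = run_reconstruction(img, roi, lls, weights=[1.0],
                                 mode="localized", n=4, opt=opt)
        assert res.rho.shape == (8, 8)
        assert res.rho.min() >= 0.01 - 1e-12
        assert res.rho.max() <= 1.0 + 1e-12
        # MMA tracks the bound with bounded transient excursions (its
        # rational approximation of the quadratic g is not conservative);
        # feasibility must hold at convergence
        assert np.all(res.g_history <= 4 * 0.01)
        assert res.g_final <= 0.01 + 1e-3
        assert res.f_history.size == res.iterations

    def test_determinism(self, tiny_setup):
        img, m, f, roi, lls = tiny_setup
        opt = OptimizerParams(max_iters=25)
        a = run_reconstruction(img, roi, lls, weights=[1.0], mode="localized",
                               n=4, opt=opt)
        b = run_reconstruction(img, roi, lls, weights=[1.0], mode="localized",
                               n=4, opt=opt)
        assert np.array_equal(a.rho, b.rho)
        assert np.array_equal(a.f_history, b.f_history)

    def test_global_mode_matches_full_model_compliance(self, desk_phantom):
        """The condensed-exterior analysis equals a direct full solve."""
        from trabtopo.phantom import default_load_cases, distribute_load
        from trabtopo.reconstruct import _GlobalProblem
        from trabtopo.refine import build_refined_global_model
        from trabtopo.workbench import roi_preset

        image, lm = desk_phantom
        params = MaterialParams()
        roi = roi_preset(image, lm, "neck", 8)
        rgm = build_refined_global_model(image, roi, 2, params)
        cases = default_load_cases()
        loads = np.stack([distribute_load(c, lm, rgm.model) for c in cases])
        weights = [c.weight for c in cases]
        gp = _GlobalProblem(rgm, loads, weights)
        moduli = simp_modulus(np.clip(rgm.rho0 * 1.1, 0.01, 1.0), params)
        f_schur, _ = gp.analyze(moduli)

        full = rgm.model.moduli.copy()
        full[rgm.design_eids] = moduli
        K = fem.assemble(rgm.model, full)
        f_direct = 0.0
        for j, w in enumerate(weights):
            u = fem.solve(rgm.model, loads[j], K=K)
            f_direct += w * 0.5 * float(loads[j] @ u)
        assert f_schur == pytest.approx(f_direct, rel=1e-8)

    def test_checkerboard_suppression(self, tiny_setup):
        img, m, f, roi, lls = tiny_setup
        opt = OptimizerParams(max_iters=80)
        res = run_reconstruction(img, roi, lls, weights=[1.0], mode="localized",
                                 n=6, opt=opt)
        # 2x2 windows strictly alternating solid (>0.9) and void (<0.1)
        hi, lo = res.rho > 0.9, res.rho < 0.1
        h00, h01, h10, h11 = hi[:-1, :-1], hi[:-1, 1:], hi[1:, :-1], hi[1:, 1:]
        l00, l01, l10, l11 = lo[:-1, :-1], lo[:-1, 1:], lo[1:, :-1], lo[1:, 1:]
        checker = (h00 & h11 & l01 & l10) | (l00 & l11 & h01 & h10)
        assert checker.mean() <= 0.01
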