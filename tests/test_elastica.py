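import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize, minimize_scalar

from pfwave import elastica as el

from conftest import THETA23, total_potential


class TestSolveEquilibrium:
    def test_unloaded_state_is_relaxed(self, params_factory):
        for n in (1, 3, 5):
            p = params_factory(n)
            s = el.solve_equilibrium(p, 0.0)
            assert np.array_equal(s.joint_angles_rad, np.full(n, p.relaxed_angle_rad))
            res, _ = el._torque_residual(s.joint_angles_rad, p, 0.0)
            assert np.max(np.abs(res)) == 0.0

    def test_single_joint_matches_1d_energy_minimum(self, params_factory):
        # oracle: minimize 1/2 k (t - ti)^2 + F r sin(t) over t
        p = params_factory(1, theta_i=0.4014)
        opt = minimize_scalar(
            lambda t: 0.5 * 176 * (t - 0.4014) ** 2 + 2.0 * 8.2 * math.sin(t),
            bounds=(-1.0, 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        s = el.solve_equilibrium(p, 2.0)
        assert s.joint_angles_rad[0] == pytest.approx(opt.x, abs=1e-8)
        assert s.joint_angles_rad[0] == pytest.approx(0.3127, abs=5e-4)
        h, _ = el.tip_metrics(s, p)
        assert h == pytest.approx(2.52, abs=0.01)

    def test_straight_chain_small_angle_deflection(self, params_factory):
        # cantilever-chain closed form: delta = (F r^2 / k) N(N+1)(2N+1)/6
        p = params_factory(3, theta_i=0.0)
        s = el.solve_equilibrium(p, 0.1)
        h, _ = el.tip_metrics(s, p)
        expected = 0.1 * 8.2**2 / 176.0 * (3 * 4 * 7 / 6)
        assert -h == pytest.approx(expected, rel=0.01)
        assert -h == pytest.approx(0.535, abs=0.002)

    def test_residual_tolerance_met(self, params_factory):
        p = params_factory(4)
        s = el.solve_equilibrium(p, 3.0)
        res, _ = el._torque_residual(s.joint_angles_rad, p, 3.0)
        assert np.max(np.abs(res)) <= el.RESIDUAL_TOL_PN_NM

    def test_negative_force_rejected(self, params_factory):
        with pytest.raises(ValueError):
            el.solve_equilibrium(params_factory(2), -1.0)

    def test_nonconvergence_raises(self, params_factory):
        # load far beyond any solvable branch for a five-dimer curl
        with pytest.raises(el.ConvergenceError):
            el.solve_equilibrium(params_factory(5), 1e6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 4),
        kappa=st.floats(50.0, 400.0),
        theta_i=st.floats(0.05, 0.6),
        lam=st.floats(0.0, 0.15),
    )
    def test_torque_balance_matches_energy_minimization(
        self, n, kappa, theta_i, lam
    ):
        """Equilibria are minima of spring energy + F * tip height."""
        p = el.ElasticaParams(
            segment_length_nm=8.2,
            relaxed_angle_rad=theta_i,
            kappa_pn_nm_per_rad=kappa,
            n_segments=n,
        )
        force = lam * kappa / 8.2
        s = el.solve_equilibrium(p, force)
        ref = minimize(
            total_potential,
            x0=np.full(n, theta_i),
            args=(p, force),
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        assert np.max(np.abs(s.joint_angles_rad - ref.x)) < 1e-6


class TestTipMetrics:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (1, 8.2 * math.sin(THETA23)),
            (2, 9.103),
            (3, 16.758),
            (4, 24.953),
        ],
    )
    def test_unloaded_height_closed_form(self, params_factory, n, expected):
        p = params_factory(n)
        s = el.solve_equilibrium(p, 0.0)
        h, _ = el.tip_metrics(s, p)
        assert h == pytest.approx(expected, abs=5e-3)
        assert h == pytest.approx(el.unloaded_tip_height(n, THETA23, 8.2), abs=1e-12)

    def test_straight_chain(self, params_factory):
        p = params_factory(4, theta_i=0.0)
        s = el.CurlState(joint_angles_rad=np.zeros(4), applied_force_pn=0.0)
        h, ext = el.tip_metrics(s, p)
        assert h == 0.0
        assert ext == pytest.approx(4 * 8.2)

    def test_mismatched_state_rejected(self, params_factory):
        s = el.CurlState(joint_angles_rad=np.zeros(2), applied_force_pn=0.0)
        with pytest.raises(ValueError):
            el.tip_metrics(s, params_factory(3))


class TestForceDeflectionCurve:
    def test_single_point_grid(self, params_factory):
        c = el.force_deflection_curve(params_factory(2), np.array([0.0]))
        assert c.force_pn.size == 1
        assert c.tip_height_nm[0] == pytest.approx(9.103, abs=5e-3)

    def test_heights_non_increasing_and_truncated_positive(self, params_factory):
        c = el.force_deflection_curve(params_factory(3))
        assert np.all(np.diff(c.tip_height_nm) < 0)
        assert np.all(c.tip_height_nm > 0)
        assert c.tip_height_nm[0] == pytest.approx(
            el.unloaded_tip_height(3, THETA23, 8.2), abs=1e-12
        )

    def test_known_point_on_curve(self, params_factory):
        p = params_factory(1, theta_i=0.4014)
        c = el.force_deflection_curve(p, np.arange(0.0, 4.0001, 0.1))
        assert c.height_at(2.0) == pytest.approx(2.52, abs=0.01)

    def test_monotone_inversion_round_trip(self, params_factory):
        c = el.force_deflection_curve(params_factory(2))
        f = 2.37
        assert c.force_at(c.height_at(f)) == pytest.approx(f, abs=1e-9)

    def test_bad_grids_rejected(self, params_factory):
        p = params_factory(2)
        with pytest.raises(ValueError):
            el.force_deflection_curve(p, np.array([]))
        with pytest.raises(ValueError):
            el.force_deflection_curve(p, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            el.force_deflection_curve(p, np.array([0.0, 0.5, 0.4]))

    def test_unloaded_height_increases_with_length(self, params_factory):
        heights = [
            el.force_deflection_curve(params_factory(n), np.array([0.0])).tip_height_nm[0]
            for n in range(1, 6)
        ]
        assert np.all(np.diff(heights) > 0)

    def test_master_curve_matches_direct_solution(self, params_factory):
        p = params_factory(3, kappa=240.0)
        direct = el.force_deflection_curve(p, np.arange(0.0, 4.001, 0.25))
        master = el.fd_curve_from_unit_curve(p)
        assert np.max(
            np.abs(direct.tip_height_nm - master.height_at(direct.force_pn))
        ) < 1e-3


class TestElasticEnergy:
    def test_unloaded_energy_zero(self, params_factory):
        p = params_factory(3)
        s = el.solve_equilibrium(p, 0.0)
        assert el.elastic_energy(s, p) == 0.0

    def test_single_joint_quadratic(self, params_factory):
        p = params_factory(1)
        s = el.CurlState(
            joint_angles_rad=np.array([p.relaxed_angle_rad + 0.1]),
            applied_force_pn=0.0,
        )
        assert el.elastic_energy(s, p) == pytest.approx(0.88)

    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_virtual_work_consistency(self, params_factory, n):
        """Stored spring energy equals the work integral along the FD curve."""
        p = params_factory(n)
        grid = np.arange(0.0, 3.0001, 0.005)
        c = el.force_deflection_curve(p, grid)
        f_end = c.force_pn[-1]
        s = el.solve_equilibrium(p, f_end)
        energy = el.elastic_energy(s, p)
        work = -np.trapezoid(c.force_pn, c.tip_height_nm)
        assert work == pytest.approx(energy, rel=1e-3)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"segment_length_nm": 0.0},
            {"kappa_pn_nm_per_rad": -5.0},
            {"relaxed_angle_rad": 1.7},
            {"relaxed_angle_rad": -0.1},
            {"n_segments": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(
            segment_length_nm=8.2,
            relaxed_angle_rad=THETA23,
            kappa_pn_nm_per_rad=176.0,
            n_segments=2,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            el.ElasticaParams(**base)
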