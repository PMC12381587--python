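import numpy as np
import pytest

from silkflight import (
    BodyKinematics,
    FourierWaveform,
    WingKinematics,
    aero_power,
    frame_chain,
    inertial_force,
    lift_drag_coeffs,
    rotational_coeff,
    simulate_wingstroke,
    strip_forces,
    strip_state,
    total_aero,
)
from silkflight.trim import trim_cost

from conftest import steady_translation_config

RHO = 1.225


class TestCoefficients:
    @pytest.mark.parametrize(
        "alpha_v, CL, CD",
        [
            (0.0, 0.0, 0.0),
            (90.0, 0.0, 3.598),
            (45.0, 1.38588, 1.30189),  # direct evaluation of the polynomials
        ],
    )
    def test_lift_drag_polynomials(self, alpha_v, CL, CD):
        cl, cd = lift_drag_coeffs(alpha_v)
        assert cl == pytest.approx(CL, abs=1e-4)
        assert cd == pytest.approx(CD, abs=1e-4)

    def test_kL_kD_scale_linearly(self):
        cl1, cd1 = lift_drag_coeffs(30.0)
        cl2, cd2 = lift_drag_coeffs(30.0, kL=1.7, kD=0.6)
        assert cl2 == pytest.approx(1.7 * cl1)
        assert cd2 == pytest.approx(0.6 * cd1)

    @pytest.mark.parametrize(
        "e, CR", [(0.75, 0.0), (0.25, np.pi / 2), (0.0, 0.75 * np.pi)]
    )
    def test_rotational_coefficient(self, e, CR):
        assert rotational_coeff(e) == pytest.approx(CR)

    def test_rotational_coefficient_domain(self):
        with pytest.raises(ValueError):
            rotational_coeff(1.2)


class TestFrameChain:
    def make_kin(self, phi=0.0, beta=0.0, alpha=0.0, betar=0.0, f=10.0):
        const = lambda v: FourierWaveform.constant(v, f)
        wing = WingKinematics(phi=const(phi), theta=const(0.0), alpha=const(alpha),
                              beta=const(beta), betar=betar, f=f)
        body = BodyKinematics(chi=const(0.0), u=const(0.0), w=const(0.0))
        return wing, body

    def test_zero_angles_identity(self):
        wing, body = self.make_kin()
        fc = frame_chain(wing, body, 0.0)
        np.testing.assert_allclose(fc["R_gw"][0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fc["omega"][0], 0.0, atol=1e-12)

    def test_vertical_stroke_plane_normal_faces_forward(self):
        # at beta = 90 deg the stroke plane is vertical: its normal
        # (z-axis) maps onto global +x, self-consistent with the inverse
        wing, body = self.make_kin(beta=90.0)
        fc = frame_chain(wing, body, 0.0)
        np.testing.assert_allclose(fc["R_gs"][0] @ [0, 0, 1], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fc["R_gs"][0] @ fc["R_gs"][0].T, np.eye(3), atol=1e-12)

    def test_left_right_mirror_symmetry(self):
        wing, body = self.make_kin(phi=30.0, beta=40.0, alpha=70.0, betar=3.0)
        right = frame_chain(wing, body, 0.01, side="right")
        left = frame_chain(wing, body, 0.01, side="left")
        M = np.diag([1.0, -1.0, 1.0])
        np.testing.assert_allclose(
            left["R_gw"][0], M @ right["R_gw"][0] @ M, atol=1e-12
        )


class TestStripState:
    @pytest.mark.parametrize("alpha_deg, expect", [(0.0, 0.0), (90.0, 90.0), (180.0, 180.0)])
    def test_angle_of_attack_limits(self, alpha_deg, expect):
        # fixed incidence: chord anti-parallel / perpendicular / parallel
        # to the relative airflow
        cfg = steady_translation_config(alpha_deg=alpha_deg, V=2.0)
        st_ = strip_state(cfg, t=0.0, strip=100)
        assert st_.alpha_v_deg == pytest.approx(expect, abs=1e-9)
        assert st_.speed == pytest.approx(2.0)

    def test_alpha_h_is_alpha_minus_beta(self, luna_moth):
        st_ = strip_state(luna_moth, t=0.013, strip=50)
        wk = luna_moth.wing_kin
        expected = wk.alpha(0.013) - wk.beta(0.013)
        assert st_.alpha_h_deg == pytest.approx(expected)

    def test_unit_vectors(self, luna_moth):
        st_ = strip_state(luna_moth, t=0.007, strip=120)
        for v in (st_.chord_dir, st_.normal, st_.airflow):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)


class TestStripForces:
    def test_hand_evaluated_lift_magnitude(self):
        # 1/2 * 1.225 * CL(45) * 2^2 * 0.02 * 5e-4 = 3.3955e-5 N
        cfg = steady_translation_config(alpha_deg=45.0, V=2.0, chord=0.02, R=0.1)
        fd = strip_forces(cfg, t=0.0, strip=0)
        assert np.linalg.norm(fd.F_L) == pytest.approx(3.3955e-5, rel=1e-3)

    def test_rates_zero_kill_rotational_and_added_mass(self):
        cfg = steady_translation_config()
        fd = strip_forces(cfg, t=0.0, strip=10)
        assert np.linalg.norm(fd.F_rot) == 0.0
        assert np.linalg.norm(fd.F_adm) == 0.0

    def test_lift_perpendicular_drag_parallel_to_airflow(self, luna_moth):
        st_ = strip_state(luna_moth, t=0.004, strip=150)
        fd = strip_forces(luna_moth, t=0.004, strip=150)
        assert abs(np.dot(fd.F_L, st_.airflow)) <= 1e-12 * np.linalg.norm(fd.F_L)
        drag_dir = fd.F_D / np.linalg.norm(fd.F_D)
        np.testing.assert_allclose(drag_dir, st_.airflow, atol=1e-12)


class TestTotalAero:
    def test_fixed_incidence_closed_form_oracle(self):
        # rectangular wing, steady translation: total lift and drag over
        # both wings must match 1/2 rho C V^2 (2S) closed forms
        V, S = 2.0, 0.002
        cfg = steady_translation_config(alpha_deg=45.0, V=V)
        F, _ = total_aero(cfg, 0.0)
        CL, CD = lift_drag_coeffs(45.0)
        drag = F[0]  # airflow is -x, so drag is along -x... and lift +/-z
        lift = F[2]
        assert abs(drag + 0.5 * RHO * CD * V**2 * 2 * S) <= 1e-3 * abs(drag)
        assert abs(abs(lift) - 0.5 * RHO * CL * V**2 * 2 * S) <= 1e-3 * abs(lift)

    def test_forces_linear_in_density(self, luna_moth):
        F1, M1 = total_aero(luna_moth, 0.005)
        cfg2 = luna_moth.replace(rho=2 * luna_moth.rho)
        F2, M2 = total_aero(cfg2, 0.005)
        np.testing.assert_allclose(F2, 2 * F1, rtol=1e-12)
        np.testing.assert_allclose(M2, 2 * M1, rtol=1e-12)

    def test_translational_forces_scale_with_v_squared(self):
        F1, _ = total_aero(steady_translation_config(V=2.0), 0.0)
        F2, _ = total_aero(steady_translation_config(V=4.0), 0.0)
        np.testing.assert_allclose(F2, 4 * F1, rtol=1e-9)


class TestSymmetry:
    def test_mirrored_wings_cancel_lateral_components(self, luna_moth):
        """Explicitly computing both kinematic chains, the lateral force
        and the roll/yaw moments vanish to machine precision."""
        res = simulate_wingstroke(
            luna_moth, n_steps=200, n_strips=50, explicit_both_wings=True
        )
        scale = luna_moth.weight * luna_moth.scalars.r2
        assert np.abs(res.F_total[:, 1]).max() <= 1e-12 * luna_moth.weight
        assert np.abs(res.M_total[:, 0]).max() <= 1e-12 * scale
        assert np.abs(res.M_total[:, 2]).max() <= 1e-12 * scale

    def test_mirror_fast_path_equals_explicit(self, luna_moth):
        a = simulate_wingstroke(luna_moth, n_steps=100, n_strips=30,
                                explicit_both_wings=True)
        b = simulate_wingstroke(luna_moth, n_steps=100, n_strips=30,
                                explicit_both_wings=False)
        np.testing.assert_array_equal(a.F_total, b.F_total)
        np.testing.assert_array_equal(a.M_total, b.M_total)
        np.testing.assert_array_equal(a.P_aer, b.P_aer)


class TestInertialForce:
    def test_constant_velocity_gives_zero(self):
        cfg = steady_translation_config()
        np.testing.assert_allclose(inertial_force(cfg, 0.01), 0.0, atol=1e-15)

    def test_periodic_wingstroke_average_vanishes(self, luna_moth):
        res = simulate_wingstroke(luna_moth, n_steps=500, n_strips=50)
        peak = np.linalg.norm(res.F_inertial, axis=1).max()
        mean = np.linalg.norm(res.F_inertial.mean(axis=0))
        assert mean <= 1e-9 * peak

    def test_oscillating_body_velocity_reaction_sign(self):
        # body position x(t) = A sin(w t): the reaction on the body from
        # the wing mass is +m A w^2 sin(w t)
        from dataclasses import replace as drep

        f, A = 10.0, 0.01
        om = 2 * np.pi * f
        cfg = steady_translation_config(f=f)
        morph = drep(cfg.morph, wing_mass=1e-4)
        u = FourierWaveform(a0=0.0, a=np.array([A * om, 0, 0]), b=np.zeros(3), f=f)
        cfg = cfg.replace(morph=morph)
        cfg = cfg.replace(body_kin=drep(cfg.body_kin, u=u))
        t = 1 / (4 * f)  # sin(w t) = 1
        Fx = inertial_force(cfg, t)[0]
        assert Fx == pytest.approx(2 * 1e-4 * A * om**2, rel=1e-9)


class TestPower:
    def test_steady_drag_dissipation(self):
        # pure translation: P = |F_D| * V, positive (dissipation), and
        # lift contributes nothing
        V = 2.0
        cfg = steady_translation_config(V=V)
        F, _ = total_aero(cfg, 0.0)
        drag_mag = abs(F[0])
        assert aero_power(cfg, 0.0) == pytest.approx(drag_mag * V, rel=1e-9)

    def test_lift_never_contributes(self, luna_moth):
        res = simulate_wingstroke(luna_moth, n_steps=300, n_strips=50)
        assert np.abs(res.P_lift_residual).max() <= 1e-12 * np.abs(res.P_aer).max()

    def test_zero_airflow_zero_power(self):
        cfg = steady_translation_config(V=0.0)
        assert aero_power(cfg, 0.0) == 0.0


class TestWingstroke:
    def test_grid_refinement_on_averages(self, luna_moth):
        r1 = simulate_wingstroke(luna_moth, n_steps=500)
        r2 = simulate_wingstroke(luna_moth, n_steps=1000)
        assert r1.Fz_mean == pytest.approx(r2.Fz_mean, rel=1e-3)
        assert r1.P_mean == pytest.approx(r2.P_mean, rel=1e-3)

    def test_defaults(self, luna_moth):
        res = simulate_wingstroke(luna_moth)
        assert res.times.size == 1000
        assert luna_moth.morph.n_strips == 200
        assert res.times[-1] < 1.0 / luna_moth.f

    def test_trim_cost_of_result_matches_definition(self, luna_moth):
        res = simulate_wingstroke(luna_moth, n_steps=200, n_strips=40)
        mg = luna_moth.weight
        r2 = luna_moth.scalars.r2
        G = trim_cost(res, luna_moth.mt, luna_moth.g, r2)
        expected = (
            (res.Fx_mean / mg) ** 2
            + (res.Fz_mean / mg - 1) ** 2
            + (res.My_mean / (mg * r2)) ** 2
        )
        assert G == pytest.approx(expected, rel=1e-12)
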