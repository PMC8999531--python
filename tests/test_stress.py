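"""Line loads, internal actions, stress profiles and peak extraction."""

import numpy as np
import pytest

import implantbar as ib
from implantbar.errors import LayoutError, ParameterError
from conftest import solve_tooth


def _central_load_case(cfg):
    layout = cfg.implant_array()
    c = ib.center_of_rigidity(layout)
    load = ib.LoadCase(P=100.0, X_p=c.X_C, Y_p=c.Y_C)
    return ib.analyze(layout, cfg.bone_bed(), load)


def test_section_properties_reference_implant():
    sec = ib.section_properties(d=4.0, H=10.0)
    assert round(sec.S0, 1) == 12.6
    assert round(sec.Sl, 1) == 125.7
    assert sec.W == pytest.approx(2 * np.pi, rel=1e-14)  # pi d^3 / 32 at d = 4
    assert sec.J == pytest.approx(np.pi * 4.0**4 / 64, rel=1e-14)
    assert ib.section_properties(d=2.0, H=10.0).S0 == pytest.approx(np.pi, rel=1e-14)


def test_section_properties_reject_nonpositive():
    with pytest.raises(ParameterError):
        ib.section_properties(d=-4.0, H=10.0)


def test_displacement_profile_central_load_is_pure_settlement(v1):
    result = _central_load_case(v1)
    zeta = result.stresses.zeta
    for i in range(1, 5):
        u = ib.implant_displacement_profile(result.kinematics, result.central, i, zeta)
        np.testing.assert_allclose(u[0], 0.0, atol=1e-18)
        np.testing.assert_allclose(u[1], 0.0, atol=1e-18)
        np.testing.assert_allclose(u[2], result.kinematics.delta[2], rtol=1e-14)


def test_displacement_profile_horizontal_components_vanish_mid_implant(v2_tooth6):
    r = v2_tooth6
    mid = np.array([0.0])
    for i in range(1, 5):
        u = ib.implant_displacement_profile(r.kinematics, r.central, i, mid)
        assert abs(u[0, 0]) < 1e-18 and abs(u[1, 0]) < 1e-18


def test_displacement_profile_rejects_bad_index(v2_tooth6):
    with pytest.raises(LayoutError):
        ib.implant_displacement_profile(
            v2_tooth6.kinematics, v2_tooth6.central, 5, np.array([0.0])
        )


def test_line_loads_satisfy_vertical_equilibrium(v1, v2):
    for cfg in (v1, v2):
        for tooth in (1, 4, 7):
            r = solve_tooth(cfg, tooth)
            H = cfg.H
            # exact polynomial integrals: int q dz = c0 * H
            axial_total = r.profile.coeffs[:, 2, 0].sum() * H
            assert axial_total == pytest.approx(r.load.P, rel=1e-12)
            # horizontal line loads are odd in zeta: zero resultant per implant
            horiz = r.profile.coeffs[:, :2, 0] * H
            np.testing.assert_allclose(horiz, 0.0, atol=1e-12 * r.load.P)


def test_line_loads_central_case_uniform_share(v1):
    r = _central_load_case(v1)
    np.testing.assert_allclose(r.profile.q[:, 2, :], 100.0 / (4 * 10.0), rtol=1e-13)
    np.testing.assert_allclose(r.profile.q[:, :2, :], 0.0, atol=1e-18)


def test_internal_actions_free_apex_and_neck_values(v2_tooth6):
    r = v2_tooth6
    # apex of every implant carries no force or moment (free end)
    np.testing.assert_allclose(r.actions.Q[:, :, 0], 0.0, atol=1e-12)
    np.testing.assert_allclose(r.actions.M[:, :, 0], 0.0, atol=1e-12)
    # axial force at the neck equals the implant's load share
    central = r.central
    radii = ib.effective_radii(central, 2.7, 10.0)
    x_p, y_p = central.pole
    share = 0.25 + x_p * central.points[:, 0] / radii.ay2 + y_p * central.points[:, 1] / radii.ax2
    np.testing.assert_allclose(r.actions.Q[:, 2, -1], -r.load.P * share, rtol=1e-12)
    # bending moment about xi at the neck: P gamma y_p H^2 / (12 ax2)
    expected_M = r.load.P * 2.7 * y_p * 10.0**2 / (12 * radii.ax2)
    np.testing.assert_allclose(r.actions.M[:, 0, -1], expected_M, rtol=1e-12)
    # vertical load produces no torque
    np.testing.assert_array_equal(r.actions.M[:, 2, :], 0.0)


def test_stress_profiles_central_load(v1):
    r = _central_load_case(v1)
    sec = r.section
    zeta = r.stresses.zeta
    # no bending: both outer fibres carry the same axial stress, which grows
    # linearly from 0 at the free apex to -P/(4 S0) ~ -1.99 MPa at the neck
    np.testing.assert_array_equal(r.stresses.sigma_minus, r.stresses.sigma_plus)
    expected = -100.0 / (4 * sec.S0) * (zeta / 10.0 + 0.5)
    np.testing.assert_allclose(r.stresses.sigma_plus, np.tile(expected, (4, 1)), atol=1e-14)
    assert r.stresses.sigma_plus[0, -1] == pytest.approx(-1.989, abs=1e-3)
    # uniform interface shear ~ 0.199 MPa, no normal interface stress
    np.testing.assert_allclose(r.stresses.sigma_tau, 100.0 / (4 * sec.Sl), rtol=1e-12)
    np.testing.assert_allclose(r.stresses.sigma_n, 0.0, atol=1e-15)


def test_normal_interface_stress_vanishes_mid_implant(v2_tooth6):
    mid = v2_tooth6.stresses.zeta.size // 2  # zeta = 0 on the odd grid
    assert v2_tooth6.stresses.zeta[mid] == 0.0
    np.testing.assert_allclose(v2_tooth6.stresses.sigma_n[:, mid], 0.0, atol=1e-15)


def test_axial_stress_at_outer_fibre_matches_extreme_profile(v2_tooth6):
    r = v2_tooth6
    for i in range(1, 5):
        Mx = r.actions.M[i - 1, 0, -1]
        My = r.actions.M[i - 1, 1, -1]
        norm = np.hypot(Mx, My)
        xi, eta = (r.section.d / 2) * np.array([My, Mx]) / norm
        sigma = ib.axial_stress_at(r.actions, r.section, i, xi, eta)
        assert sigma[-1] == pytest.approx(r.stresses.sigma_plus[i - 1, -1], rel=1e-12)


def test_peaks_at_neck_and_match_closed_form(v1, v2):
    for cfg in (v1, v2):
        for tooth in range(1, 8):
            r = solve_tooth(cfg, tooth)
            assert np.all(r.peaks.zeta_implant == cfg.H / 2)
            assert np.all(r.peaks.zeta_bone == cfg.H / 2)
            impl, bone = ib.neck_stresses_closed_form(
                r.central, 2.7, r.load, r.section
            )
            np.testing.assert_allclose(r.peaks.implant, impl, rtol=1e-12)
            np.testing.assert_allclose(r.peaks.bone, bone, rtol=1e-12)


def test_stresses_independent_of_bed_modulus_and_thickness(v2):
    """Stress fields depend on the bed only through gamma; displacements
    scale with the bed rigidities."""
    layout = v2.implant_array()
    load = v2.load_cases()[5]
    ref = ib.analyze(layout, ib.BoneBed(nu_b=0.35, E_b=1000.0, h=0.1), load)
    for E_b, h in [(500.0, 0.1), (4000.0, 0.1), (1000.0, 0.05), (1000.0, 0.4)]:
        alt = ib.analyze(layout, ib.BoneBed(nu_b=0.35, E_b=E_b, h=h), load)
        np.testing.assert_allclose(alt.stresses.eq_impl, ref.stresses.eq_impl, rtol=1e-12)
        np.testing.assert_allclose(alt.stresses.eq_bone, ref.stresses.eq_bone, rtol=1e-12)
        np.testing.assert_allclose(alt.stresses.sigma_plus, ref.stresses.sigma_plus, rtol=1e-12)
        scale = (E_b / 1000.0) / (h / 0.1)
        np.testing.assert_allclose(alt.kinematics.delta, ref.kinematics.delta / scale, rtol=1e-12)


def test_stresses_scale_exactly_with_load(v2):
    layout = v2.implant_array()
    base = v2.load_cases()[5]
    r1 = ib.analyze(layout, v2.bone_bed(), base)
    r5 = ib.analyze(
        layout, v2.bone_bed(), ib.LoadCase(P=5 * base.P, X_p=base.X_p, Y_p=base.Y_p)
    )
    np.testing.assert_allclose(r5.stresses.eq_impl, 5 * r1.stresses.eq_impl, rtol=1e-12)
    np.testing.assert_allclose(r5.stresses.eq_bone, 5 * r1.stresses.eq_bone, rtol=1e-12)


def test_mirror_symmetry_swaps_implant_roles(v2):
    """Reflecting the pole across the sagittal plane swaps implants
    1 <-> 4 and 2 <-> 3 with identical stress magnitudes."""
    layout = v2.implant_array()
    load = v2.load_cases()[5]
    mirrored = ib.LoadCase(P=load.P, X_p=-load.X_p, Y_p=load.Y_p)
    r = ib.analyze(layout, v2.bone_bed(), load)
    m = ib.analyze(layout, v2.bone_bed(), mirrored)
    swap = [3, 2, 1, 0]
    np.testing.assert_allclose(m.peaks.implant, r.peaks.implant[swap], rtol=1e-12)
    np.testing.assert_allclose(m.peaks.bone, r.peaks.bone[swap], rtol=1e-12)
    np.testing.assert_allclose(m.stresses.eq_impl, r.stresses.eq_impl[swap], rtol=1e-12)


def test_distal_pole_monotonically_loads_supporting_implant(v1, v2):
    for cfg in (v1, v2):
        peaks = [solve_tooth(cfg, t).peaks.bone[3] for t in range(4, 8)]
        assert np.all(np.diff(peaks) >= 0)


def test_action_profiles_satisfy_rod_equilibrium(v2_tooth6):
    """Finite differences of Q and M recover -q and the shear terms."""
    r = v2_tooth6
    zeta = r.stresses.zeta
    for i in range(4):
        dQ = np.gradient(r.actions.Q[i], zeta, axis=-1, edge_order=2)
        np.testing.assert_allclose(dQ, -r.profile.q[i], atol=1e-9 * np.abs(r.profile.q).max())
        dMx = np.gradient(r.actions.M[i, 0], zeta, edge_order=2)
        dMy = np.gradient(r.actions.M[i, 1], zeta, edge_order=2)
        scale = max(np.abs(r.actions.Q[i]).max(), 1.0)
        np.testing.assert_allclose(dMx, -r.actions.Q[i, 1], atol=5e-3 * scale)
        np.testing.assert_allclose(dMy, r.actions.Q[i, 0], atol=5e-3 * scale)


def test_equivalent_maxima_tie_breaks_to_lowest_index(v1):
    r = _central_load_case(v1)  # all four implants load identically
    assert r.peaks.governing_implant == 1
    assert r.peaks.governing_bone == 1


def test_strength_assessment_verdicts_and_margins(v2_tooth7):
    a = v2_tooth7.assessment
    assert a is not None
    # titanium implant is safe everywhere, bone fails at the supporting implant
    assert bool(np.all(a.implant_ok))
    assert not a.bone_ok[3]
    assert v2_tooth7.peaks.governing_bone == 4
    assert not a.ok
    np.testing.assert_allclose(
        a.bone_margin, a.limits.allow_bone / v2_tooth7.peaks.bone, rtol=1e-12
    )


def test_strength_limits_reject_nonpositive():
    with pytest.raises(ParameterError):
        ib.StrengthLimits(allow_impl=0.0, allow_bone=3.0)


def test_allowable_load_is_exact_by_linearity(v2):
    layout = v2.implant_array()
    load7 = v2.load_cases()[6]
    limits = v2.limits()
    p_max = ib.allowable_load(layout, v2.bone_bed(), load7, limits)
    # the bone criterion governs: at P_max the peak equals the allowable
    at_pmax = ib.analyze(
        layout, v2.bone_bed(), ib.LoadCase(P=p_max, X_p=load7.X_p, Y_p=load7.Y_p)
    )
    assert at_pmax.peaks.bone_max == pytest.approx(limits.allow_bone, rel=1e-12)
    assert p_max == pytest.approx(85.84, abs=0.05)
    # the recommended reduced load is safe at tooth 7
    r80 = ib.analyze(
        layout, v2.bone_bed(),
        ib.LoadCase(P=80.0, X_p=load7.X_p, Y_p=load7.Y_p), limits,
    )
    assert r80.assessment.ok
    # doubling both allowables doubles the bound
    double = ib.StrengthLimits(allow_impl=300.0, allow_bone=6.0)
    assert ib.allowable_load(layout, v2.bone_bed(), load7, double) == pytest.approx(
        2 * p_max, rel=1e-12
    )


def test_max_loadable_tooth(v1, v2):
    assert ib.max_loadable_tooth(
        v1.implant_array(), v1.bone_bed(), v1.load_cases(), v1.limits()
    ) == 7
    assert ib.max_loadable_tooth(
        v2.implant_array(), v2.bone_bed(), v2.load_cases(), v2.limits()
    ) == 6
    generous = ib.StrengthLimits(allow_impl=1e9, allow_bone=1e9)
    assert ib.max_loadable_tooth(
        v2.implant_array(), v2.bone_bed(), v2.load_cases(), generous
    ) == 7
    hopeless = ib.StrengthLimits(allow_impl=150.0, allow_bone=0.1)
    assert ib.max_loadable_tooth(
        v2.implant_array(), v2.bone_bed(), v2.load_cases(), hopeless
    ) == 0
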