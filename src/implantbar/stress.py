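"""Line loads, internal actions and stress profiles along each implant.

Once the rigid-frame kinematics are known, every implant ``i`` carries a
distributed bed reaction ``q_i(zeta) = -C (delta + theta x r_i(zeta))``
that is exactly linear in the axial coordinate ``zeta``.  Treating the
implant as a rod under axial force and bilateral bending, the internal
force and moment profiles follow from::

    dQ/dzeta + q = 0,       dM/dzeta + Q x k = 0,

integrated from the apex ``zeta = -H/2`` (free of contact load) upward.
Because ``q`` is a first-degree polynomial the integrals are evaluated
exactly: ``Q`` is quadratic and ``M`` cubic in ``zeta``.

Stresses:

* implant axial stress in the outermost fibres,
  ``sigma_zeta^± = Q_zeta / S0 ± |M_bend| / W`` (MPa, compression < 0);
* bone interface stresses ``sigma_n = |q_perp| / (pi d)`` (normal) and
  ``sigma_tau = q_zeta / (pi d)`` (tangential);
* equivalent stresses ``max(|sigma^+|, |sigma^-|)`` for the titanium
  implant (maximum-normal-stress criterion) and the von Mises measure
  ``sqrt(sigma_n^2 + 3 sigma_tau^2)`` for the bone interface.

Both equivalent stresses peak at the implant neck ``zeta = H/2``.  The
final stress expressions contain the bed only through the rigidity ratio
``gamma``: scaling ``E_b`` or ``h`` at fixed ``gamma`` changes the frame
displacements but not a single stress value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .errors import LayoutError, ParameterError
from .model_core import (
    BedCoefficients,
    CentralLayout,
    EffectiveRadii,
    FrameKinematics,
    LoadCase,
    effective_radii,
)

#: default number of axial evaluation points on [-H/2, H/2]
GRID_SIZE = 101


def zeta_grid(H: float, n: int = GRID_SIZE) -> np.ndarray:
    """``n`` equispaced axial stations from the apex to the neck, inclusive."""
    if n < 2:
        raise ParameterError(f"grid must have at least 2 points, got {n}")
    return np.linspace(-H / 2.0, H / 2.0, n)


@dataclass(frozen=True)
class SectionGeometry:
    """Cross-section constants of a cylindrical implant (mm-based units):
    area ``S0``, lateral surface ``Sl``, section modulus ``W`` and second
    moment ``J`` (equal about both transverse axes)."""

    d: float
    H: float
    S0: float
    Sl: float
    W: float
    J: float


def section_properties(d: float, H: float) -> SectionGeometry:
    """``S0 = pi d^2/4``, ``Sl = pi d H``, ``J = pi d^4/64``, ``W = J/(d/2)``."""
    if not d > 0 or not H > 0:
        raise ParameterError(f"d and H must be positive, got d={d}, H={H}")
    J = np.pi * d**4 / 64.0
    return SectionGeometry(
        d=d,
        H=H,
        S0=np.pi * d * d / 4.0,
        Sl=np.pi * d * H,
        W=J / (d / 2.0),
        J=J,
    )


@dataclass(frozen=True, eq=False)
class LineLoadProfile:
    """Bed reactions on each implant, N/mm.

    ``q[i, c, k]`` is component ``c`` (xi, eta, zeta) of the line load on
    implant ``i`` at axial station ``zeta[k]``.  ``coeffs[i, c]`` holds the
    exact polynomial coefficients ``(constant, slope)`` in ``zeta``; the
    horizontal components are linear and odd contributors, the axial one is
    constant.  ``points`` are the central implant coordinates, retained so
    that equilibrium can be checked from the profile alone.
    """

    zeta: np.ndarray
    q: np.ndarray
    coeffs: np.ndarray | None
    points: np.ndarray
    H: float

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True, eq=False)
class InternalActions:
    """Internal force ``Q[i, c, k]`` (N) and moment ``M[i, c, k]`` (N mm)
    profiles; ``Qpoly``/``Mpoly`` are the per-implant, per-component
    :class:`numpy.polynomial.Polynomial` closed forms."""

    zeta: np.ndarray
    Q: np.ndarray
    M: np.ndarray
    Qpoly: list
    Mpoly: list


@dataclass(frozen=True, eq=False)
class StressProfile:
    """Per-implant stress profiles (MPa) on the axial grid: outer-fibre
    axial stresses ``sigma_plus``/``sigma_minus``, bone interface stresses
    ``sigma_n``/``sigma_tau`` and the two equivalent stresses."""

    zeta: np.ndarray
    sigma_plus: np.ndarray
    sigma_minus: np.ndarray
    sigma_n: np.ndarray
    sigma_tau: np.ndarray
    eq_impl: np.ndarray
    eq_bone: np.ndarray


@dataclass(frozen=True, eq=False)
class PeakStresses:
    """Peak equivalent stresses per implant and where they occur."""

    implant: np.ndarray  # MPa, per implant
    bone: np.ndarray  # MPa, per implant
    zeta_implant: np.ndarray  # mm, argmax location per implant
    zeta_bone: np.ndarray
    governing_implant: int  # 1-based index of the implant peak
    governing_bone: int

    @property
    def implant_max(self) -> float:
        return float(self.implant[self.governing_implant - 1])

    @property
    def bone_max(self) -> float:
        return float(self.bone[self.governing_bone - 1])


@dataclass(frozen=True)
class StrengthLimits:
    """Allowable stresses: ``allow_impl`` for the implant material (first,
    maximum-normal-stress theory) and ``allow_bone`` for the bone interface
    (fourth, von Mises energy theory), MPa."""

    allow_impl: float
    allow_bone: float

    def __post_init__(self) -> None:
        if not self.allow_impl > 0 or not self.allow_bone > 0:
            raise ParameterError(
                f"allowable stresses must be positive, got "
                f"({self.allow_impl}, {self.allow_bone})"
            )


@dataclass(frozen=True, eq=False)
class Assessment:
    """Strength verdicts against the allowable stresses."""

    peaks: PeakStresses
    limits: StrengthLimits
    implant_ok: np.ndarray  # bool per implant
    bone_ok: np.ndarray
    implant_margin: np.ndarray  # allowable / peak, inf on zero stress
    bone_margin: np.ndarray

    @property
    def ok(self) -> bool:
        return bool(np.all(self.implant_ok) and np.all(self.bone_ok))


def implant_displacement_profile(
    kin: FrameKinematics,
    central: CentralLayout,
    i: int,
    zeta: np.ndarray,
) -> np.ndarray:
    """Displacement vectors ``u_i(zeta)`` (mm) of implant ``i`` (1-based),
    shape ``(3, len(zeta))``: horizontal components linear in ``zeta``,
    vertical constant along the implant."""
    if not 1 <= i <= central.n:
        raise LayoutError(f"implant index {i} outside 1..{central.n}")
    x, y = central.points[i - 1]
    r = np.stack([np.full_like(zeta, x), np.full_like(zeta, y), zeta])
    return kin.delta[:, None] + np.cross(kin.theta, r.T).T


def line_load_profile(
    kin: FrameKinematics,
    central: CentralLayout,
    coeffs: BedCoefficients,
    zeta: np.ndarray | None = None,
) -> LineLoadProfile:
    """Bed reaction line loads ``q_i(zeta) = -C u_i(zeta)`` for all implants.

    The exact polynomial coefficients are stored alongside the sampled
    values; the horizontal components vanish for a centrally applied load
    and integrate to zero over the implant length for any load.
    """
    if zeta is None:
        zeta = zeta_grid(central.H)
    n = central.n
    Cn, Ct = coeffs.C_n, coeffs.C_t
    dx, dy, dz = kin.delta
    tx, ty, tz = kin.theta
    poly = np.zeros((n, 3, 2))  # [implant, component, (const, slope)]
    for k, (x, y) in enumerate(central.points):
        # u = delta + theta x r, r = (x, y, zeta)
        poly[k, 0] = (-Cn * (dx - tz * y), -Cn * ty)  # q_xi
        poly[k, 1] = (-Cn * (dy + tz * x), Cn * tx)  # q_eta
        poly[k, 2] = (-Ct * (dz + tx * y - ty * x), 0.0)  # q_zeta
    q = poly[:, :, 0, None] + poly[:, :, 1, None] * zeta[None, None, :]
    return LineLoadProfile(zeta=zeta, q=q, coeffs=poly, points=central.points.copy(), H=central.H)


def internal_actions(profile: LineLoadProfile) -> InternalActions:
    """Integrate the rod equilibrium equations exactly from the apex.

    ``Q = -int q`` with ``Q(-H/2) = 0``; the bending moments follow from
    ``dM_xi/dzeta = -Q_eta`` and ``dM_eta/dzeta = +Q_xi`` with
    ``M(-H/2) = 0``.  The torque is identically zero: the line loads act
    through the implant axis.
    """
    if profile.coeffs is None:
        raise ParameterError("internal actions need the exact line-load polynomials")
    a = -profile.H / 2.0
    zeta = profile.zeta
    n = profile.n
    Q = np.zeros((n, 3, zeta.size))
    M = np.zeros((n, 3, zeta.size))
    Qpoly, Mpoly = [], []
    for i in range(n):
        qp = [Polynomial(profile.coeffs[i, c]) for c in range(3)]
        Qp = [-(p.integ(lbnd=a)) for p in qp]
        Mp = [
            -(Qp[1].integ(lbnd=a)),  # M_xi
            Qp[0].integ(lbnd=a),  # M_eta
            Polynomial([0.0]),  # M_zeta
        ]
        Qpoly.append(Qp)
        Mpoly.append(Mp)
        for c in range(3):
            Q[i, c] = Qp[c](zeta)
            M[i, c] = Mp[c](zeta)
    return InternalActions(zeta=zeta, Q=Q, M=M, Qpoly=Qpoly, Mpoly=Mpoly)


def stress_profiles(
    actions: InternalActions,
    section: SectionGeometry,
    profile: LineLoadProfile,
) -> StressProfile:
    """Implant outer-fibre and bone interface stress profiles (MPa)."""
    bend = np.hypot(actions.M[:, 0, :], actions.M[:, 1, :])
    axial = actions.Q[:, 2, :] / section.S0
    sigma_plus = axial + bend / section.W
    sigma_minus = axial - bend / section.W
    pid = np.pi * section.d
    sigma_n = np.hypot(profile.q[:, 0, :], profile.q[:, 1, :]) / pid
    sigma_tau = profile.q[:, 2, :] / pid
    eq_impl = np.maximum(np.abs(sigma_plus), np.abs(sigma_minus))
    eq_bone = np.sqrt(sigma_n**2 + 3.0 * sigma_tau**2)
    return StressProfile(
        zeta=actions.zeta,
        sigma_plus=sigma_plus,
        sigma_minus=sigma_minus,
        sigma_n=sigma_n,
        sigma_tau=sigma_tau,
        eq_impl=eq_impl,
        eq_bone=eq_bone,
    )


def axial_stress_at(
    actions: InternalActions, section: SectionGeometry, i: int, xi: float, eta: float
) -> np.ndarray:
    """Axial stress profile at an arbitrary cross-section point
    ``(xi, eta)`` of implant ``i`` (1-based):
    ``Q_zeta/S0 + M_eta xi / J + M_xi eta / J``."""
    if not 1 <= i <= actions.Q.shape[0]:
        raise LayoutError(f"implant index {i} outside 1..{actions.Q.shape[0]}")
    k = i - 1
    return (
        actions.Q[k, 2, :] / section.S0
        + actions.M[k, 1, :] * xi / section.J
        + actions.M[k, 0, :] * eta / section.J
    )


def _last_argmax(a: np.ndarray) -> int:
    """Index of the maximum, preferring the highest axial station on ties
    (the neck, where the analytical argmax sits)."""
    return a.size - 1 - int(np.argmax(a[::-1]))


def equivalent_maxima(stress: StressProfile) -> PeakStresses:
    """Per-implant peaks of the two equivalent stresses and the governing
    implant (lowest index on exact ties)."""
    n = stress.eq_impl.shape[0]
    impl = np.empty(n)
    bone = np.empty(n)
    z_impl = np.empty(n)
    z_bone = np.empty(n)
    for i in range(n):
        ki = _last_argmax(stress.eq_impl[i])
        kb = _last_argmax(stress.eq_bone[i])
        impl[i] = stress.eq_impl[i, ki]
        bone[i] = stress.eq_bone[i, kb]
        z_impl[i] = stress.zeta[ki]
        z_bone[i] = stress.zeta[kb]
    return PeakStresses(
        implant=impl,
        bone=bone,
        zeta_implant=z_impl,
        zeta_bone=z_bone,
        governing_implant=int(np.argmax(impl)) + 1,
        governing_bone=int(np.argmax(bone)) + 1,
    )


def neck_stresses_closed_form(
    central: CentralLayout,
    gamma: float,
    load: LoadCase,
    section: SectionGeometry,
    radii: EffectiveRadii | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form peak equivalent stresses at the implant neck.

    For the sagittally symmetric layout the maxima over ``zeta`` admit the
    explicit forms (per implant ``i``, share factor
    ``s_i = 1/4 + x_p x_i / ay2 + y_p y_i / ax2`` and bending measure
    ``b = sqrt((H x_p / ay2)^2 + (H y_p / ax2)^2)``)::

        implant:  (P/S0) * max over sign of |s_i ± (2/3) gamma (H/d) b|
        bone:     (P/Sl) * sqrt(gamma^2/4 * b^2 + 3 s_i^2)

    Returns ``(implant_peaks, bone_peaks)`` as per-implant arrays (MPa).
    """
    if central.pole is None:
        raise ParameterError("central layout carries no pole")
    if radii is None:
        radii = effective_radii(central, gamma, central.H)
    H = central.H
    x_p, y_p = central.pole
    x = central.points[:, 0]
    y = central.points[:, 1]
    share = 0.25 + x_p * x / radii.ay2 + y_p * y / radii.ax2
    b = np.hypot(H * x_p / radii.ay2, H * y_p / radii.ax2)
    bend = (2.0 / 3.0) * gamma * (H / section.d) * b
    impl = (load.P / section.S0) * np.maximum(np.abs(share + bend), np.abs(share - bend))
    bone = (load.P / section.Sl) * np.sqrt(gamma**2 / 4.0 * b**2 + 3.0 * share**2)
    return impl, bone


def strength_assessment(peaks: PeakStresses, limits: StrengthLimits) -> Assessment:
    """Compare peak equivalent stresses with the allowable values.

    The implant passes under the maximum-normal-stress criterion, the bone
    under the von Mises criterion; margins are ``allowable / peak``.
    """
    with np.errstate(divide="ignore"):
        impl_margin = np.where(peaks.implant > 0, limits.allow_impl / peaks.implant, np.inf)
        bone_margin = np.where(peaks.bone > 0, limits.allow_bone / peaks.bone, np.inf)
    return Assessment(
        peaks=peaks,
        limits=limits,
        implant_ok=peaks.implant <= limits.allow_impl,
        bone_ok=peaks.bone <= limits.allow_bone,
        implant_margin=impl_margin,
        bone_margin=bone_margin,
    )
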