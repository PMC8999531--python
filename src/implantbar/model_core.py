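"""Rigid-frame statics of a bar-splinted dental implant array on an elastic bed.

The mechanical system is a complete overdenture whose metal bar rigidly
splints four parallel, vertical, cylindrical implants placed in the
edentulous mandible.  Because the metal framework is orders of magnitude
stiffer than bone, the assembly "implants + bar + denture base" is treated
as a single absolutely rigid body with six degrees of freedom: three
translations ``(dx, dy, dz)`` of the centre of rigidity and three small
rotations ``(tx, ty, tz)`` about the central axes.  Each implant is coupled
to the jawbone through a thin elastic interface layer obeying Winkler's
hypothesis: the contact line load is proportional to the local relative
displacement, with a normal bed rigidity ``C_n`` acting on horizontal
motion of the implant axis and a tangential rigidity ``C_t`` acting on
vertical (axial) motion.

Coordinate conventions
----------------------
* Original frame ``OXYZ``: origin at the middle of the dental arch, ``Z``
  upward, ``X`` distal, ``Y`` oral.  Implant ``i`` occupies the vertical
  segment ``(X_i, Y_i, Z)``, ``Z in [-H, 0]``.
* Central frame ``Cxyz``: origin at the centre of rigidity — the centroid
  of the implant positions at mid-implant depth ``Z = -H/2`` — with axes
  parallel to the original ones.  The axial coordinate ``zeta`` runs over
  ``[-H/2, H/2]``; ``zeta = H/2`` is the implant neck.
* Units: mm, N and MPa (N/mm^2) throughout.  The mastication load ``P``
  acts in ``-Z``; compressive axial stresses are negative.

For a layout that is mirror-symmetric about the sagittal plane ``x = 0``
the 6x6 rigid-body stiffness is diagonal and the kinematics have a
closed form (:func:`solve_frame_symmetric`).  Arbitrary layouts —
irregular quadrangles, or three and more implants — are handled by
:func:`solve_frame_general`, which assembles the stiffness by exact
integration along each implant and solves the linear system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError, ParameterError, RankError, SymmetryError

#: mirror-match tolerance (mm) for the closed-form symmetric path
SYMMETRY_TOL = 1e-9

#: condition-number ceiling beyond which the assembled stiffness is
#: declared rank-deficient
_COND_LIMIT = 1e12


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise LayoutError("implant layout must be an (n, 2) array of planar points")
    if pts.shape[0] < 3:
        raise LayoutError(f"need at least 3 implants, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise LayoutError("implant coordinates must be finite")
    return pts


def _mirror_symmetric(pts: np.ndarray, tol: float) -> bool:
    """True if the centred point set is invariant under x -> -x."""
    centred = pts - pts.mean(axis=0)
    unmatched = list(range(len(centred)))
    for i in range(len(centred)):
        if i not in unmatched:
            continue
        xi, yi = centred[i]
        partner = None
        for j in unmatched:
            xj, yj = centred[j]
            if abs(xi + xj) <= tol and abs(yi - yj) <= tol:
                partner = j
                break
        if partner is None:
            return False
        unmatched.remove(i)
        if partner != i:
            unmatched.remove(partner)
    return True


@dataclass(frozen=True, eq=False)
class ImplantArray:
    """Planar layout of parallel vertical implants of equal size.

    Parameters
    ----------
    points
        ``(n, 2)`` original coordinates ``(X_i, Y_i)`` in mm, one row per
        implant, ordered by the clinical labels 1..n.
    H
        Implant length, mm.
    d
        Implant diameter, mm.
    """

    points: np.ndarray
    H: float
    d: float

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        # coincident implants make the layout physically meaningless
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) < 1e-9:
                    raise LayoutError(f"implants {i + 1} and {j + 1} coincide")
        object.__setattr__(self, "points", pts)
        if not self.H > 0:
            raise ParameterError(f"implant length H must be positive, got {self.H}")
        if not self.d > 0:
            raise ParameterError(f"implant diameter d must be positive, got {self.d}")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def is_sagittally_symmetric(self, tol: float = SYMMETRY_TOL) -> bool:
        """Whether the closed-form path applies: exactly four implants,
        mirror-symmetric about the sagittal plane after centring."""
        return self.n == 4 and _mirror_symmetric(self.points, tol)


@dataclass(frozen=True)
class Center:
    """Centre of rigidity of the implant system, original coordinates (mm)."""

    X_C: float
    Y_C: float
    Z_C: float


@dataclass(frozen=True, eq=False)
class CentralLayout:
    """Implant layout (and optionally the load pole) in central coordinates.

    ``points`` sum to zero in both planar coordinates by construction;
    ``pole`` is the mastication-load application point ``(x_p, y_p)``.
    """

    points: np.ndarray
    pole: np.ndarray | None
    H: float
    d: float

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def is_sagittally_symmetric(self, tol: float = SYMMETRY_TOL) -> bool:
        return self.n == 4 and _mirror_symmetric(self.points, tol)


@dataclass(frozen=True)
class BoneBed:
    """Elastic interface layer between implant and bone.

    ``E_b`` is the height-averaged Young's modulus of the (cortical +
    trabecular) bone in MPa, ``nu_b`` its Poisson ratio and ``h`` the
    thickness of the thin interface layer in mm (``h << d``).  Final
    stresses do not depend on ``E_b`` or ``h`` — only displacements do —
    so the defaults are placeholders of a realistic order of magnitude.
    """

    nu_b: float = 0.35
    E_b: float = 1000.0
    h: float = 0.1

    def __post_init__(self) -> None:
        if not self.E_b > 0:
            raise ParameterError(f"bone modulus E_b must be positive, got {self.E_b}")
        if not 0.0 <= self.nu_b < 0.5:
            raise ParameterError(f"Poisson ratio nu_b must lie in [0, 0.5), got {self.nu_b}")
        if not self.h > 0:
            raise ParameterError(f"layer thickness h must be positive, got {self.h}")


@dataclass(frozen=True)
class BedCoefficients:
    """Winkler bed rigidities: ``C_n`` (normal), ``C_t`` (tangential), N/mm^2,
    and their ratio ``gamma = C_n / C_t = 2 (1 + nu_b)``."""

    C_n: float
    C_t: float
    gamma: float


@dataclass(frozen=True)
class LoadCase:
    """Vertical mastication force of magnitude ``P`` (N, acting in -Z)
    applied at the pole ``(X_p, Y_p)`` — the centre of a denture tooth."""

    P: float
    X_p: float
    Y_p: float
    tooth: int | None = None

    def __post_init__(self) -> None:
        if not self.P > 0:
            raise ParameterError(f"load magnitude P must be positive, got {self.P}")


@dataclass(frozen=True)
class EffectiveRadii:
    """Squared effective radii of the layout (mm^2): the rotational
    stiffnesses about the central axes are ``C_t * a^2 * H`` (x, y) and
    ``C_n * az2 * H`` (z)."""

    ax2: float
    ay2: float
    az2: float


@dataclass(frozen=True, eq=False)
class FrameKinematics:
    """Rigid-frame solution: centre translations ``delta`` (mm) and small
    rotations ``theta`` (rad), both in the central frame."""

    delta: np.ndarray
    theta: np.ndarray

    def displacement(self, point) -> np.ndarray:
        """Displacement ``u = delta + theta x r`` of a frame point ``r``."""
        r = np.asarray(point, dtype=float)
        return self.delta + np.cross(self.theta, r)


@dataclass(frozen=True, eq=False)
class StiffnessMatrix:
    """Assembled 6-DOF system ``K @ (delta, theta) = rhs`` in the ordering
    ``(dx, dy, dz, tx, ty, tz)``."""

    matrix: np.ndarray
    rhs: np.ndarray


def center_of_rigidity(layout: ImplantArray) -> Center:
    """Centre of rigidity of a four-implant system.

    Planar coordinates are the centroid of the implant positions; the
    vertical coordinate sits at mid-implant depth ``-H/2``.
    """
    if layout.n != 4:
        raise LayoutError(f"centre of rigidity is defined for 4 implants, got {layout.n}")
    X_C, Y_C = layout.points.mean(axis=0)
    return Center(float(X_C), float(Y_C), -0.5 * layout.H)


def centralize(layout: ImplantArray, load: LoadCase | None = None) -> CentralLayout:
    """Translate layout (and pole) into the central coordinate system.

    The centre is always recomputed from the implant coordinates of the
    given layout, never taken from user input.
    """
    centroid = layout.points.mean(axis=0)
    points = layout.points - centroid
    pole = None
    if load is not None:
        pole = np.array([load.X_p, load.Y_p], dtype=float) - centroid
    return CentralLayout(points=points, pole=pole, H=layout.H, d=layout.d)


def bed_coefficients(bed: BoneBed, d: float, gamma: float | None = None) -> BedCoefficients:
    """Winkler bed rigidities for an implant of diameter ``d``.

    ``C_n = E_b * pi * d / h`` and ``C_t = C_n / gamma`` with
    ``gamma = 2 (1 + nu_b)``.  ``gamma`` may be overridden to study the
    sensitivity of the stress field to the rigidity ratio (stresses depend
    on the bed only through ``gamma``).
    """
    if not d > 0:
        raise ParameterError(f"implant diameter d must be positive, got {d}")
    g = 2.0 * (1.0 + bed.nu_b) if gamma is None else float(gamma)
    if not g > 0:
        raise ParameterError(f"rigidity ratio gamma must be positive, got {g}")
    C_n = bed.E_b * np.pi * d / bed.h
    return BedCoefficients(C_n=float(C_n), C_t=float(C_n / g), gamma=g)


def effective_radii(central: CentralLayout, gamma: float, H: float) -> EffectiveRadii:
    """Squared effective radii of a centred layout.

    ``ax2 = sum(y_i^2) + gamma H^2 / 3`` and symmetrically for ``ay2``;
    ``az2 = sum(x_i^2) + sum(y_i^2)`` (exercised only by torsion, which a
    vertical load never excites).
    """
    x = central.points[:, 0]
    y = central.points[:, 1]
    gH2_3 = gamma * H * H / 3.0
    return EffectiveRadii(
        ax2=float(np.sum(y * y) + gH2_3),
        ay2=float(np.sum(x * x) + gH2_3),
        az2=float(np.sum(x * x) + np.sum(y * y)),
    )


def solve_frame_symmetric(
    central: CentralLayout,
    coeffs: BedCoefficients,
    load: LoadCase,
) -> FrameKinematics:
    """Closed-form 6-DOF solution for a sagittally symmetric 4-implant layout.

    With mirror symmetry the central axes are principal and the stiffness
    matrix is diagonal, giving::

        dz = -P / (4 C_t H)
        tx = -P y_p / (C_t ax2 H)
        ty =  P x_p / (C_t ay2 H)

    and ``dx = dy = tz = 0`` exactly: a vertical load produces no
    horizontal frame motion and no torsion.
    """
    if central.pole is None:
        raise ParameterError("central layout carries no pole; centralize with the load case")
    if not central.is_sagittally_symmetric():
        raise SymmetryError(
            "layout is not mirror-symmetric about the sagittal plane; "
            "use solve_frame_general"
        )
    H = central.H
    radii = effective_radii(central, coeffs.gamma, H)
    x_p, y_p = central.pole
    P = load.P
    dz = -P / (4.0 * coeffs.C_t * H)
    tx = -P * y_p / (coeffs.C_t * radii.ax2 * H)
    ty = P * x_p / (coeffs.C_t * radii.ay2 * H)
    return FrameKinematics(
        delta=np.array([0.0, 0.0, dz]),
        theta=np.array([tx, ty, 0.0]),
    )


def assemble_system(
    central: CentralLayout,
    coeffs: BedCoefficients,
    load: LoadCase,
) -> StiffnessMatrix:
    """Assemble the 6x6 rigid-body stiffness and load vector exactly.

    Each implant contributes ``int A(z)^T C A(z) dz`` over ``[-H/2, H/2]``
    with ``A = [I | -[r]_x]``, ``r = (x_i, y_i, z)`` and
    ``C = diag(C_n, C_n, C_t)``.  The integrands are at most quadratic in
    ``z``, so the block integrals are closed-form (``int z dz = 0``,
    ``int z^2 dz = H^3/12``).  For a centred layout the translation-rotation
    coupling always vanishes; mirror asymmetry shows up only as the product
    of inertia ``sum(x_i y_i)`` coupling the two tilts.
    """
    H = central.H
    Cn, Ct = coeffs.C_n, coeffs.C_t
    I2 = H**3 / 12.0  # int z^2 dz
    K = np.zeros((6, 6))
    x = central.points[:, 0]
    y = central.points[:, 1]
    n = central.n
    K[0, 0] = K[1, 1] = n * Cn * H
    K[2, 2] = n * Ct * H
    # translation-rotation coupling (nonzero only if the layout is uncentred)
    K[0, 5] = K[5, 0] = -Cn * H * np.sum(y)
    K[1, 5] = K[5, 1] = Cn * H * np.sum(x)
    K[2, 3] = K[3, 2] = Ct * H * np.sum(y)
    K[2, 4] = K[4, 2] = -Ct * H * np.sum(x)
    K[3, 3] = n * Cn * I2 + Ct * H * np.sum(y * y)
    K[4, 4] = n * Cn * I2 + Ct * H * np.sum(x * x)
    K[3, 4] = K[4, 3] = -Ct * H * np.sum(x * y)
    K[5, 5] = Cn * H * np.sum(x * x + y * y)
    if central.pole is None:
        raise ParameterError("central layout carries no pole; centralize with the load case")
    x_p, y_p = central.pole
    # vertical force -P k at the pole: moment r_p x P = (-P y_p, P x_p, 0)
    rhs = np.array([0.0, 0.0, -load.P, -load.P * y_p, load.P * x_p, 0.0])
    return StiffnessMatrix(matrix=K, rhs=rhs)


def solve_frame_general(
    layout: ImplantArray,
    coeffs: BedCoefficients,
    load: LoadCase,
) -> FrameKinematics:
    """6-DOF solution for an arbitrary layout (irregular quadrangle, or
    three and more implants) under a vertical load.

    Reduces to :func:`solve_frame_symmetric` on symmetric layouts.  Raises
    :class:`RankError` when the assembled stiffness is singular (e.g. a
    single implant free to spin about its own axis).
    """
    central = centralize(layout, load)
    system = assemble_system(central, coeffs, load)
    cond = np.linalg.cond(system.matrix)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise RankError(f"degenerate layout: stiffness condition number {cond:.3g}")
    sol = np.linalg.solve(system.matrix, system.rhs)
    return FrameKinematics(delta=sol[:3].copy(), theta=sol[3:].copy())


def rigid_point_displacement(kin: FrameKinematics, point) -> np.ndarray:
    """Small displacement of a rigid-frame point: ``u = delta + theta x r``."""
    return kin.displacement(point)
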