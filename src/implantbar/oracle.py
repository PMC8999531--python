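"""Brute-force discretized solver used to cross-validate the closed forms.

Each implant is replaced by ``N`` short segments; every segment midpoint
carries an independent triplet of Winkler springs of per-length rigidity
``(C_n, C_n, C_t)``.  The 6x6 rigid-body stiffness is then assembled by
midpoint quadrature and solved numerically, and the bed reactions are
sampled at the segment midpoints.  Nothing here reuses the analytical
integrals, so agreement with the closed-form path (second-order in
``1/N``; exact for the constant-reaction central-load case) is an
independent check, and the solver doubles as a fallback for layouts and
load directions outside the closed form's scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, RankError
from .model_core import (
    BedCoefficients,
    FrameKinematics,
    ImplantArray,
    LoadCase,
    centralize,
)
from .stress import LineLoadProfile

#: default number of segments per implant
DEFAULT_SEGMENTS = 1000


@dataclass(frozen=True, eq=False)
class DiscretizedBed:
    """Spring discretization of the interface layer: per-implant segment
    midpoints, common segment length and per-length rigidities."""

    zeta_mid: np.ndarray  # (N,)
    seg_len: float
    C_n: float
    C_t: float


@dataclass(frozen=True, eq=False)
class EquilibriumReport:
    """Residuals of the global force and moment balance."""

    force_residual: np.ndarray  # (3,) N
    moment_residual: np.ndarray  # (3,) N mm
    relative_residual: float


def discretize_bed(H: float, coeffs: BedCoefficients, N: int) -> DiscretizedBed:
    if N < 2:
        raise ParameterError(f"need at least 2 segments, got {N}")
    seg = H / N
    mids = -H / 2.0 + seg * (np.arange(N) + 0.5)
    return DiscretizedBed(zeta_mid=mids, seg_len=seg, C_n=coeffs.C_n, C_t=coeffs.C_t)


def discretized_frame_solve(
    layout: ImplantArray,
    coeffs: BedCoefficients,
    load: LoadCase,
    N: int = DEFAULT_SEGMENTS,
    direction=(0.0, 0.0, -1.0),
) -> tuple[FrameKinematics, LineLoadProfile]:
    """Solve the 6-DOF system assembled from ``N`` springs per implant.

    ``direction`` is the unit load direction (default vertical, downward);
    non-vertical directions are accepted for robustness testing even
    though the analytical pipeline restricts itself to vertical loads.
    The load line of action passes through the pole at mid-implant depth
    (``z = 0`` in central coordinates), consistent with the analytical
    moment ``r_p x P``.

    Returns the kinematics and the bed-reaction profile sampled at the
    segment midpoints (no exact polynomial attached).
    """
    central = centralize(layout, load)
    bedd = discretize_bed(layout.H, coeffs, N)
    C = np.diag([bedd.C_n, bedd.C_n, bedd.C_t])
    K = np.zeros((6, 6))
    for x, y in central.points:
        for z in bedd.zeta_mid:
            A = np.hstack([np.eye(3), -_skew(np.array([x, y, z]))])
            K += bedd.seg_len * (A.T @ C @ A)
    dirv = np.asarray(direction, dtype=float)
    dirv = dirv / np.linalg.norm(dirv)
    F = load.P * dirv
    r_p = np.array([central.pole[0], central.pole[1], 0.0])
    rhs = np.concatenate([F, np.cross(r_p, F)])
    cond = np.linalg.cond(K)
    if not np.isfinite(cond) or cond > 1e12:
        raise RankError(f"degenerate layout: stiffness condition number {cond:.3g}")
    sol = np.linalg.solve(K, rhs)
    kin = FrameKinematics(delta=sol[:3].copy(), theta=sol[3:].copy())
    q = np.empty((central.n, 3, N))
    for i, (x, y) in enumerate(central.points):
        r = np.stack([np.full(N, x), np.full(N, y), bedd.zeta_mid])
        u = kin.delta[:, None] + np.cross(kin.theta, r.T).T
        q[i] = -(C @ u)
    profile = LineLoadProfile(
        zeta=bedd.zeta_mid, q=q, coeffs=None, points=central.points.copy(), H=layout.H
    )
    return kin, profile


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def equilibrium_residual(
    profile: LineLoadProfile,
    load: LoadCase,
    pole_central,
    direction=(0.0, 0.0, -1.0),
) -> EquilibriumReport:
    """Residual of the six global balance equations.

    The bed reactions (integrated exactly from the stored polynomials, or
    by midpoint sums for a discrete profile) must cancel the applied load
    and its moment about the centre.  The relative residual scales the
    force error by ``P`` and the moment error by ``P * L`` with ``L`` the
    larger of the implant length and layout extent.
    """
    dirv = np.asarray(direction, dtype=float)
    dirv = dirv / np.linalg.norm(dirv)
    F_applied = load.P * dirv
    r_p = np.array([pole_central[0], pole_central[1], 0.0])
    M_applied = np.cross(r_p, F_applied)

    F_bed = np.zeros(3)
    M_bed = np.zeros(3)
    if profile.coeffs is not None:
        H = profile.H
        m0 = profile.coeffs[:, :, 0] * H  # int q dz, per implant/component
        m1 = profile.coeffs[:, :, 1] * H**3 / 12.0  # int z q dz
        for i, (x, y) in enumerate(profile.points):
            F_bed += m0[i]
            # int (x, y, z) x q dz component-wise
            M_bed += np.array(
                [
                    y * m0[i, 2] - m1[i, 1],
                    m1[i, 0] - x * m0[i, 2],
                    x * m0[i, 1] - y * m0[i, 0],
                ]
            )
    else:
        w = profile.H / profile.zeta.size
        for i, (x, y) in enumerate(profile.points):
            r = np.stack([np.full_like(profile.zeta, x), np.full_like(profile.zeta, y), profile.zeta])
            F_bed += w * profile.q[i].sum(axis=1)
            M_bed += w * np.cross(r.T, profile.q[i].T).sum(axis=0)

    force_res = F_bed + F_applied
    moment_res = M_bed + M_applied
    L = max(profile.H, float(np.abs(profile.points).max()), 1.0)
    rel = max(
        float(np.linalg.norm(force_res)) / load.P,
        float(np.linalg.norm(moment_res)) / (load.P * L),
    )
    return EquilibriumReport(
        force_residual=force_res, moment_residual=moment_res, relative_residual=rel
    )
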