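"""End-to-end case analysis: kinematics -> profiles -> peaks -> verdicts.

This module strings the primitives together for the questions a
prosthodontic designer actually asks: what are the stresses for a load at
tooth ``t``; is the design safe for every tooth; what is the largest safe
mastication load; how far distally may the denture be loaded.  All
stresses are exactly linear in the load magnitude ``P``, which makes the
allowable-load inversion exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    BedCoefficients,
    BoneBed,
    CentralLayout,
    FrameKinematics,
    ImplantArray,
    LoadCase,
    bed_coefficients,
    centralize,
    solve_frame_general,
    solve_frame_symmetric,
)
from .stress import (
    Assessment,
    InternalActions,
    LineLoadProfile,
    PeakStresses,
    SectionGeometry,
    StressProfile,
    StrengthLimits,
    equivalent_maxima,
    internal_actions,
    line_load_profile,
    section_properties,
    strength_assessment,
    stress_profiles,
    zeta_grid,
)

logger = logging.getLogger("implantbar")


@dataclass(frozen=True, eq=False)
class CaseResult:
    """Everything computed for one load case."""

    load: LoadCase
    central: CentralLayout
    kinematics: FrameKinematics
    section: SectionGeometry
    profile: LineLoadProfile
    actions: InternalActions
    stresses: StressProfile
    peaks: PeakStresses
    assessment: Assessment | None


def analyze(
    layout: ImplantArray,
    bed: BoneBed,
    load: LoadCase,
    limits: StrengthLimits | None = None,
    *,
    gamma: float | None = None,
    grid: int = 101,
    general: bool = False,
) -> CaseResult:
    """Solve one vertical load case end to end.

    Uses the closed-form symmetric solution when the layout allows it,
    otherwise (or when ``general=True``) the assembled 6-DOF solver.
    """
    coeffs = bed_coefficients(bed, layout.d, gamma=gamma)
    central = centralize(layout, load)
    if general or not layout.is_sagittally_symmetric():
        kin = solve_frame_general(layout, coeffs, load)
    else:
        kin = solve_frame_symmetric(central, coeffs, load)
    zeta = zeta_grid(layout.H, grid)
    section = section_properties(layout.d, layout.H)
    profile = line_load_profile(kin, central, coeffs, zeta)
    actions = internal_actions(profile)
    stresses = stress_profiles(actions, section, profile)
    peaks = equivalent_maxima(stresses)
    assessment = strength_assessment(peaks, limits) if limits is not None else None
    result = CaseResult(
        load=load,
        central=central,
        kinematics=kin,
        section=section,
        profile=profile,
        actions=actions,
        stresses=stresses,
        peaks=peaks,
        assessment=assessment,
    )
    _log_solve(layout, load, result)
    return result


def _log_solve(layout: ImplantArray, load: LoadCase, result: CaseResult) -> None:
    layout_hash = hash(layout.points.round(9).tobytes()) & 0xFFFFFFFF
    verdict = ""
    if result.assessment is not None:
        verdict = " pass" if result.assessment.ok else " FAIL"
    logger.info(
        "solve layout=%08x tooth=%s P=%.6g peak_impl=%.6g peak_bone=%.6g%s",
        layout_hash,
        load.tooth,
        load.P,
        result.peaks.implant_max,
        result.peaks.bone_max,
        verdict,
    )


def sweep(
    layout: ImplantArray,
    bed: BoneBed,
    loads: list[LoadCase],
    limits: StrengthLimits | None = None,
    **kwargs,
) -> list[CaseResult]:
    """Analyze a list of load cases (e.g. the seven arch teeth)."""
    return [analyze(layout, bed, load, limits, **kwargs) for load in loads]


def allowable_load(
    layout: ImplantArray,
    bed: BoneBed,
    load: LoadCase,
    limits: StrengthLimits,
    **kwargs,
) -> float:
    """Largest vertical load (N) at the given pole that satisfies both
    strength conditions.

    Stresses are exactly linear in ``P``, so the bound is
    ``min(allow_impl / s_impl(1 N), allow_bone / s_bone(1 N))`` with the
    unit-load peaks; ``inf`` for the degenerate zero-stress case.
    """
    unit = LoadCase(P=1.0, X_p=load.X_p, Y_p=load.Y_p, tooth=load.tooth)
    result = analyze(layout, bed, unit, **kwargs)
    s_impl = result.peaks.implant_max
    s_bone = result.peaks.bone_max
    bounds = []
    if s_impl > 0:
        bounds.append(limits.allow_impl / s_impl)
    if s_bone > 0:
        bounds.append(limits.allow_bone / s_bone)
    return min(bounds) if bounds else math.inf


def max_loadable_tooth(
    layout: ImplantArray,
    bed: BoneBed,
    arch_loads: list[LoadCase],
    limits: StrengthLimits,
    **kwargs,
) -> int:
    """Most distal tooth up to which the whole dentition may be loaded.

    Returns the largest tooth index ``t`` such that *every* tooth
    ``1..t`` passes both strength conditions at its given load (a denture
    loaded "no further than tooth t" must carry safe loads everywhere
    mesial of ``t`` as well); 0 if even the first tooth fails.
    """
    results = sweep(layout, bed, arch_loads, limits, **kwargs)
    best = 0
    for load, result in zip(arch_loads, results):
        assert result.assessment is not None
        if result.assessment.ok:
            best = load.tooth if load.tooth is not None else best + 1
        else:
            break
    return best
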