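"""Bundled reference configurations and synthetic layout generators.

Two clinically representative four-implant placements are packaged as
ready-to-run study configurations, both for an edentulous mandible
restored with a bar-retained overdenture carrying a seven-tooth (right)
dental arch:

* variant 1 — a wide equilateral trapezoid (anterior implants 12 mm,
  posterior 21 mm from the midline), typical when bone supply permits
  spreading the posterior implants distally;
* variant 2 — a narrow trapezoid (6 / 16 mm half-spans) whose connecting
  bar is almost straight, so the distal cantilever lever arm is longer.

Both use 10 mm x 4 mm implants, a 100 N vertical mastication load per
tooth, bone Poisson ratio 0.35 and allowable stresses of 150 MPa
(titanium implant) and 3 MPa (bone interface).  Tooth poles run from the
central incisor (tooth 1) to the second molar (tooth 7); left-side
loading is obtained by mirroring ``X_p -> -X_p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LoadSpec, StudyConfig
from .errors import LayoutError, ParameterError
from .model_core import ImplantArray

#: (X_i, Y_i) mm — wide trapezoid, implants labelled 1..4 left-to-right
VARIANT1_IMPLANTS = ((-21.0, 17.0), (-12.0, 6.0), (12.0, 6.0), (21.0, 17.0))
#: (X_i, Y_i) mm — narrow trapezoid
VARIANT2_IMPLANTS = ((-16.0, 11.0), (-6.0, 4.0), (6.0, 4.0), (16.0, 11.0))
#: (X_p, Y_p) mm — right-side tooth poles 1 (incisor) .. 7 (second molar)
ARCH_POLES = (
    (3.0, 1.0),
    (9.0, 3.0),
    (15.0, 7.0),
    (19.0, 13.0),
    (23.0, 20.0),
    (25.0, 29.0),
    (28.0, 40.0),
)

IMPLANT_LENGTH = 10.0  # mm
IMPLANT_DIAMETER = 4.0  # mm
MASTICATION_LOAD = 100.0  # N
BONE_POISSON = 0.35
ALLOW_IMPLANT = 150.0  # MPa
ALLOW_BONE = 3.0  # MPa


@dataclass(frozen=True, eq=False)
class ArchSpec:
    """Ordered tooth poles 1..7 in original coordinates, one side of the
    arch; ``side`` selects the right half (as tabulated) or its mirror."""

    poles: np.ndarray  # (7, 2) mm
    side: str = "right"

    def __post_init__(self) -> None:
        poles = np.asarray(self.poles, dtype=float)
        if poles.shape != (7, 2):
            raise LayoutError(f"arch must list 7 tooth poles, got shape {poles.shape}")
        sign = 1.0 if self.side == "right" else -1.0
        if np.any(np.diff(sign * poles[:, 0]) < 0):
            raise LayoutError("tooth poles must advance distally (|X_p| non-decreasing)")
        object.__setattr__(self, "poles", poles)


def arch(side: str = "right") -> ArchSpec:
    """The seven-tooth arch; left-side poles mirror ``X_p -> -X_p``."""
    if side not in ("right", "left"):
        raise ParameterError(f"side must be 'right' or 'left', got {side!r}")
    poles = np.asarray(ARCH_POLES, dtype=float)
    if side == "left":
        poles = poles * np.array([-1.0, 1.0])
    return ArchSpec(poles=poles, side=side)


def reference_config(variant: int, side: str = "right") -> StudyConfig:
    """The bundled study configuration for placement variant 1 or 2."""
    if variant == 1:
        implants = VARIANT1_IMPLANTS
    elif variant == 2:
        implants = VARIANT2_IMPLANTS
    else:
        raise ParameterError(f"unknown placement variant {variant!r}; expected 1 or 2")
    poles = arch(side).poles
    return StudyConfig(
        implants=[list(p) for p in implants],
        H=IMPLANT_LENGTH,
        d=IMPLANT_DIAMETER,
        nu_b=BONE_POISSON,
        allow_impl=ALLOW_IMPLANT,
        allow_bone=ALLOW_BONE,
        loads=[
            LoadSpec(tooth=t, Xp=float(x), Yp=float(y), P=MASTICATION_LOAD)
            for t, (x, y) in enumerate(poles, start=1)
        ],
    )


def trapezoid_layout(
    posterior_halfspan: float,
    anterior_halfspan: float,
    posterior_y: float,
    anterior_y: float,
    H: float = IMPLANT_LENGTH,
    d: float = IMPLANT_DIAMETER,
) -> ImplantArray:
    """Sagittally symmetric layout at the vertices of an equilateral
    trapezoid, implants ordered 1..4 by increasing ``X``.

    ``trapezoid_layout(21, 12, 17, 6)`` reproduces the variant-1 layout.
    """
    if not posterior_halfspan > 0 or not anterior_halfspan > 0:
        raise LayoutError("trapezoid half-spans must be positive")
    if posterior_halfspan == anterior_halfspan and posterior_y == anterior_y:
        raise LayoutError("degenerate trapezoid: anterior and posterior rows coincide")
    points = [
        (-posterior_halfspan, posterior_y),
        (-anterior_halfspan, anterior_y),
        (anterior_halfspan, anterior_y),
        (posterior_halfspan, posterior_y),
    ]
    return ImplantArray(points=np.asarray(points), H=H, d=d)


def random_symmetric_trapezoid(rng: np.random.Generator) -> ImplantArray:
    """Random but clinically plausible symmetric trapezoid (for property
    tests): half-spans 4-25 mm, row offsets up to 20 mm, implants 8-14 mm
    long and 3.5-5 mm wide."""
    anterior = rng.uniform(4.0, 15.0)
    posterior = anterior + rng.uniform(1.0, 10.0)
    anterior_y = rng.uniform(2.0, 10.0)
    posterior_y = anterior_y + rng.uniform(1.0, 12.0)
    H = rng.uniform(8.0, 14.0)
    d = rng.uniform(3.5, 5.0)
    return trapezoid_layout(posterior, anterior, posterior_y, anterior_y, H=H, d=d)
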