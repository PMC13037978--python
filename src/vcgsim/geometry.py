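"""Frontal-plane coordinate system, the Einthoven triangle, and the lead axes.

Coordinate convention
---------------------
The frontal plane is parametrized by ``x`` positive toward the anatomical
*left* of the subject and ``y`` positive toward the *inferior* direction
(the feet).  With this choice the clinical hexaxial angles fall out of the
math directly: 0 deg points left (along lead I), +90 deg points inferior,
and the mean electrical axis reported by the reconstruction code can be
read as a clinical axis without sign gymnastics.  Plotting code flips the
y axis for display so loops appear in the familiar orientation.

Lengths are millimetres; lead-axis vectors are dimensionless unit vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrontalPoint",
    "TriangleConfig",
    "LeadAxes",
    "make_triangle",
    "lead_axes",
]

_SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class FrontalPoint:
    """A point in the frontal plane (mm; x toward left, y toward feet)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"FrontalPoint coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "FrontalPoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class TriangleConfig:
    """An equilateral Einthoven triangle with its centroid at the origin.

    Vertices carry the standard limb assignment: right arm (RA) upper-left,
    left arm (LA) upper-right, left leg (LL) at the bottom (y-inferior
    convention, so "upper" means negative y).
    """

    side_length: float
    vertex_RA: FrontalPoint
    vertex_LA: FrontalPoint
    vertex_LL: FrontalPoint
    centroid: FrontalPoint = field(default=FrontalPoint(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError(f"side_length must be > 0, got {self.side_length}")
        for a, b in (
            (self.vertex_RA, self.vertex_LA),
            (self.vertex_LA, self.vertex_LL),
            (self.vertex_LL, self.vertex_RA),
        ):
            d = a.distance_to(b)
            if abs(d - self.side_length) > 1e-9 * self.side_length:
                raise ValueError(
                    f"triangle is not equilateral: pairwise distance {d!r} != side {self.side_length!r}"
                )

    @property
    def vertices(self) -> dict[str, FrontalPoint]:
        return {"RA": self.vertex_RA, "LA": self.vertex_LA, "LL": self.vertex_LL}


@dataclass(frozen=True)
class LeadAxes:
    """Unit direction vectors of the three bipolar limb leads.

    In the hexaxial convention lead I points at 0 deg, lead II at +60 deg
    and lead III at +120 deg (angles from +x toward +y, i.e. toward the
    feet).  These satisfy ``u_I + u_III = u_II``, which is Einthoven's law
    ``DII = DI + DIII`` expressed as a geometric identity of the axes.
    """

    u_I: np.ndarray
    u_II: np.ndarray
    u_III: np.ndarray

    def __post_init__(self) -> None:
        for name, u in (("u_I", self.u_I), ("u_II", self.u_II), ("u_III", self.u_III)):
            if abs(np.linalg.norm(u) - 1.0) > 1e-12:
                raise ValueError(f"{name} is not a unit vector: {u}")
        if not np.allclose(self.u_I + self.u_III, self.u_II, atol=1e-12):
            raise ValueError("lead axes violate Einthoven's identity u_I + u_III = u_II")


def make_triangle(side_length: float = 100.0) -> TriangleConfig:
    """Build an equilateral Einthoven triangle centred on the origin.

    Parameters
    ----------
    side_length : float
        Edge length in millimetres; must be positive.

    Returns
    -------
    TriangleConfig
        RA = (-L/2, -L/(2*sqrt(3))), LA = (+L/2, -L/(2*sqrt(3))),
        LL = (0, L/sqrt(3)); centroid at the origin.
    """
    if side_length <= 0:
        raise ValueError(f"side_length must be > 0, got {side_length}")
    L = float(side_length)
    half_h = L / (2.0 * _SQRT3)
    return TriangleConfig(
        side_length=L,
        vertex_RA=FrontalPoint(-L / 2.0, -half_h),
        vertex_LA=FrontalPoint(+L / 2.0, -half_h),
        vertex_LL=FrontalPoint(0.0, L / _SQRT3),
    )


def lead_axes() -> LeadAxes:
    """Return the bipolar limb-lead unit axes (I at 0 deg, II at 60, III at 120)."""
    ang = np.deg2rad([0.0, 60.0, 120.0])
    u = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    # pin exact values where the trig is exact in intent but not in floats
    u[0] = (1.0, 0.0)
    u[1] = (0.5, _SQRT3 / 2.0)
    u[2] = (-0.5, _SQRT3 / 2.0)
    return LeadAxes(u_I=u[0], u_II=u[1], u_III=u[2])
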