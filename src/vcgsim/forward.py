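"""Forward models: from a cardiac dipole state to Leads DI, DII, DIII.

Two models are provided.

*Ideal projection* — the textbook picture: the heart vector (magnitude
``Vh`` volts, frontal angle ``alpha``) is projected onto the three lead
axes, ``DI = Vh cos(alpha)``, ``DII = Vh cos(alpha - 60)``,
``DIII = Vh cos(alpha - 120)``.  Einthoven's law ``DII = DI + DIII`` holds
identically.

*Resistive tank* — a software stand-in for a saline-tank teaching rig: a
point current source (the mobile electrode) and a central point sink (the
fixed "sacrifice" return electrode) in a homogeneous conductive half-space.
Electrode potentials follow the DC point-source solution and the leads are
pairwise differences of the potentials at the triangle vertices, so
Einthoven's law again holds by construction.  Because the hardware this
emulates drives the *anode* at the centre, raw lead voltages come out with
reversed polarity; the model reproduces that and `correct_polarity`
restores the standard representation.  Container-wall boundary effects and
electrode double-layer capacitance are deliberately not modelled; the tank
is a quasi-static, first-order picture.

Units: positions in millimetres (converted to metres inside the potential
formula), conductivity in S/m, current in amperes, potentials in volts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .geometry import FrontalPoint, TriangleConfig, make_triangle

__all__ = [
    "HeartVector",
    "LeadTriplet",
    "TankConfig",
    "Calibration",
    "ideal_leads",
    "point_potential",
    "tank_leads",
    "calibrate",
    "correct_polarity",
]

_MM_TO_M = 1e-3


@dataclass(frozen=True)
class HeartVector:
    """Instantaneous cardiac dipole: magnitude ``Vh`` (V, >= 0) and frontal
    angle ``alpha_deg`` in [-180, 180).

    A zero-magnitude vector has no defined direction; it is stored with the
    conventional ``alpha_deg = 0`` and ``degenerate = True``.
    """

    Vh: float
    alpha_deg: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Vh) and math.isfinite(self.alpha_deg)):
            raise ValueError("HeartVector fields must be finite")
        if self.Vh < 0:
            raise ValueError(f"Vh must be >= 0, got {self.Vh}")
        if not (-180.0 <= self.alpha_deg < 180.0):
            raise ValueError(f"alpha_deg must lie in [-180, 180), got {self.alpha_deg}")


@dataclass(frozen=True)
class LeadTriplet:
    """Simultaneous bipolar limb-lead voltages (volts), optional timestamp (s)."""

    DI: float
    DII: float
    DIII: float
    t: float | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.DI, self.DII, self.DIII)):
            raise ValueError("lead voltages must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.DI, self.DII, self.DIII], dtype=float)


@dataclass(frozen=True)
class TankConfig:
    """Virtual saline-tank geometry and physics.

    Attributes
    ----------
    triangle : TriangleConfig
        Electrode geometry (RA/LA/LL at the vertices).
    sink_position : FrontalPoint
        The fixed current-return ("sacrifice") electrode; defaults to the
        centroid, as in the hardware it abstracts.
    conductivity : float
        Medium conductivity, S/m.  Default 1.5, a reasonable value for
        0.9% saline at room temperature.
    source_current : float
        Injected current, A.  Default 1 mA.
    polarity_inverted : bool
        True (default) mirrors the central-anode wiring whose raw lead
        voltages are sign-flipped relative to the standard convention.
    half_space : bool
        True (default) uses the half-space factor 1/(2*pi*sigma) --
        electrodes at the free surface of the bath; False uses the
        full-space 1/(4*pi*sigma).
    """

    triangle: TriangleConfig = field(default_factory=make_triangle)
    sink_position: FrontalPoint | None = None
    conductivity: float = 1.5
    source_current: float = 1e-3
    polarity_inverted: bool = True
    half_space: bool = True

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise ValueError(f"conductivity must be > 0, got {self.conductivity}")
        if self.source_current == 0:
            raise ValueError("source_current must be nonzero")
        if self.sink_position is None:
            object.__setattr__(self, "sink_position", self.triangle.centroid)
        # sink must sit strictly inside the triangle
        if not _inside_triangle(self.sink_position, self.triangle):
            raise ValueError("sink_position must lie strictly inside the triangle")

    @property
    def sink(self) -> FrontalPoint:
        assert self.sink_position is not None
        return self.sink_position


@dataclass(frozen=True)
class Calibration:
    """Per-lead zero-reference offsets (volts) recorded at a known position."""

    offset_DI: float = 0.0
    offset_DII: float = 0.0
    offset_DIII: float = 0.0
    reference_position: FrontalPoint = field(default=FrontalPoint(0.0, 0.0))

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.offset_DI, self.offset_DII, self.offset_DIII)
        ):
            raise ValueError("calibration offsets must be finite")


def _inside_triangle(p: FrontalPoint, tri: TriangleConfig) -> bool:
    a, b, c = (v.as_array() for v in (tri.vertex_RA, tri.vertex_LA, tri.vertex_LL))
    q = p.as_array()

    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    s1, s2, s3 = cross(a, b, q), cross(b, c, q), cross(c, a, q)
    return (s1 > 0 and s2 > 0 and s3 > 0) or (s1 < 0 and s2 < 0 and s3 < 0)


def ideal_leads(v: HeartVector) -> LeadTriplet:
    """Project a heart vector onto the three lead axes.

    ``DI = Vh cos(alpha)``, ``DII = Vh cos(alpha - 60 deg)``,
    ``DIII = Vh cos(alpha - 120 deg)``; Einthoven's law holds exactly.
    """
    a = math.radians(v.alpha_deg)
    DI = v.Vh * math.cos(a)
    DIII = v.Vh * math.cos(a - math.radians(120.0))
    # DII from the identity, so the law holds to the last bit
    return LeadTriplet(DI=DI, DII=DI + DIII, DIII=DIII)


def point_potential(
    source: FrontalPoint,
    sink: FrontalPoint,
    field_point: FrontalPoint,
    cfg: TankConfig,
) -> float:
    """Potential (V) at ``field_point`` from a source/sink pair in the medium.

    DC point-source solution in a homogeneous medium:
    ``V = I/(2 pi sigma) * (1/r_source - 1/r_sink)`` for a half-space
    (``1/(4 pi sigma)`` for a full space), with distances in metres.
    """
    r_src = field_point.distance_to(source) * _MM_TO_M
    r_snk = field_point.distance_to(sink) * _MM_TO_M
    if r_src == 0.0 or r_snk == 0.0:
        raise ValueError("field point coincides with the source or the sink (singular potential)")
    factor = 2.0 if cfg.half_space else 4.0
    k = cfg.source_current / (factor * math.pi * cfg.conductivity)
    return k * (1.0 / r_src - 1.0 / r_snk)


def tank_leads(
    source: FrontalPoint,
    cfg: TankConfig,
    cal: Calibration | None = None,
) -> LeadTriplet:
    """Lead voltages for a mobile source electrode at ``source``.

    Potentials at RA/LA/LL come from `point_potential`; then
    ``DI = V(LA) - V(RA)``, ``DII = V(LL) - V(RA)``, ``DIII = V(LL) - V(LA)``.
    Processing order matches the acquisition chain: raw differential
    voltages, minus calibration offsets, then polarity correction.
    """
    tri = cfg.triangle
    if source.distance_to(cfg.sink) == 0.0:
        raise ValueError("source coincides with the sink electrode (singular configuration)")
    for name, vertex in tri.vertices.items():
        if source.distance_to(vertex) == 0.0:
            raise ValueError(f"source coincides with the {name} electrode (singular potential)")
    v = {
        name: point_potential(source, cfg.sink, vertex, cfg)
        for name, vertex in tri.vertices.items()
    }
    DI = v["LA"] - v["RA"]
    DII = v["LL"] - v["RA"]
    DIII = v["LL"] - v["LA"]
    if cfg.polarity_inverted:
        DI, DII, DIII = -DI, -DII, -DIII  # raw voltages as the hardware reports them
    if cal is not None:
        DI -= cal.offset_DI
        DII -= cal.offset_DII
        DIII -= cal.offset_DIII
    raw = LeadTriplet(DI=DI, DII=DII, DIII=DIII)
    return correct_polarity(raw, cfg.polarity_inverted)


def calibrate(
    samples: Sequence[LeadTriplet],
    reference_position: FrontalPoint | None = None,
) -> Calibration:
    """Estimate zero-reference offsets as the per-lead mean of ``samples``.

    The samples are raw readings taken with the source at the reference
    position (centre of the triangle in the procedure this mirrors).
    """
    if len(samples) == 0:
        raise ValueError("calibrate requires at least one sample")
    arr = np.array([s.as_array() for s in samples], dtype=float)
    mean = arr.mean(axis=0)
    return Calibration(
        offset_DI=float(mean[0]),
        offset_DII=float(mean[1]),
        offset_DIII=float(mean[2]),
        reference_position=reference_position or FrontalPoint(0.0, 0.0),
    )


def correct_polarity(t: LeadTriplet, inverted: bool) -> LeadTriplet:
    """Negate all three leads when ``inverted`` is True; identity otherwise.

    This is the software inversion that undoes the sign flip introduced by
    a central-anode wiring.  Applying it twice is the identity.
    """
    if not inverted:
        return t
    return replace(t, DI=-t.DI, DII=-t.DII, DIII=-t.DIII)
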