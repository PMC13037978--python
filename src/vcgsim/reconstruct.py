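"""Heart-vector reconstruction from lead voltages and VCG loop tracing.

The classical mean-electrical-axis relation estimates the frontal heart
vector from two limb leads:

    Vh = DI / cos(alpha),    tan(alpha) = 1/sqrt(3) + (2/sqrt(3)) * DIII/DI

Implemented here in the numerically robust Cartesian form

    vx = DI,    vy = (DI + 2*DIII) / sqrt(3)
    Vh = hypot(vx, vy),    alpha = atan2(vy, vx)

which agrees with the arctangent form wherever DI != 0 and additionally
handles DI = 0 (pure +/-90 deg axes) and the rear quadrants, where a
single-argument arctangent is blind to the sign of DI.  The derivation:
DI is the projection on the 0-deg axis, so vx = DI; DIII is the
projection on the 120-deg axis, DIII = -vx/2 + vy*sqrt(3)/2, which solves
to vy = (DI + 2*DIII)/sqrt(3).

A sign-flipped variant (``printed_signs=True``) negates vy.  It
corresponds to leads whose polarity has *not* been software-corrected
(equivalently a y-up display convention) as produced by a central-anode
acquisition chain; with standard-polarity leads the default form is the
correct one.

DII is never used for reconstruction; it is redundant under Einthoven's
law and serves only as a consistency diagnostic (`einthoven_residual`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import HeartVector, LeadTriplet

__all__ = [
    "LeadSeries",
    "VCGLoop",
    "EinthovenWarning",
    "reconstruct_vector",
    "einthoven_residual",
    "loop_from_series",
]

_SQRT3 = math.sqrt(3.0)


class EinthovenWarning(UserWarning):
    """Raised (as a warning) when DII deviates noticeably from DI + DIII."""


@dataclass(frozen=True)
class LeadSeries:
    """Uniformly sampled simultaneous DI/DII/DIII record.

    Attributes
    ----------
    fs : float
        Sampling rate, Hz (> 0).
    DI, DII, DIII : ndarray
        Equal-length voltage sequences (volts).
    t0 : float
        Time of the first sample, seconds.
    """

    fs: float
    DI: np.ndarray
    DII: np.ndarray
    DIII: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        for name in ("DI", "DII", "DIII"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.DI)
        if n < 1:
            raise ValueError("LeadSeries must contain at least one sample")
        if not (len(self.DII) == n and len(self.DIII) == n):
            raise ValueError("DI, DII, DIII must have equal lengths")
        if not all(np.all(np.isfinite(getattr(self, k))) for k in ("DI", "DII", "DIII")):
            raise ValueError("lead series values must be finite")

    def __len__(self) -> int:
        return len(self.DI)

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    def triplet(self, i: int) -> LeadTriplet:
        return LeadTriplet(
            DI=float(self.DI[i]), DII=float(self.DII[i]), DIII=float(self.DIII[i]),
            t=float(self.t0 + i / self.fs),
        )


@dataclass(frozen=True)
class VCGLoop:
    """Ordered frontal-plane trajectory of the reconstructed heart vector.

    Arrays are index-aligned with the source series: Cartesian components
    ``vx``/``vy`` (volts), magnitude ``Vh``, angle ``alpha_deg`` in
    [-180, 180), the Einthoven residual diagnostic, per-point degeneracy
    flags (True where the vector is exactly zero), and timestamps.
    """

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    Vh: np.ndarray
    alpha_deg: np.ndarray
    residual: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("vx", "vy", "Vh", "alpha_deg", "residual", "degenerate"):
            if len(getattr(self, name)) != n:
                raise ValueError("VCGLoop arrays must be index-aligned")

    def __len__(self) -> int:
        return len(self.t)


def _wrap_angle_deg(a: float) -> float:
    """Wrap to [-180, 180); the exact +180 boundary maps to -180."""
    w = math.fmod(a + 180.0, 360.0)
    if w < 0:
        w += 360.0
    return w - 180.0


def reconstruct_vector(t: LeadTriplet, printed_signs: bool = False) -> HeartVector:
    """Invert the lead projection: (DI, DIII) -> (Vh, alpha).

    Parameters
    ----------
    t : LeadTriplet
        Lead voltages; DII is ignored (redundant under Einthoven's law).
    printed_signs : bool
        Select the sign-flipped arctangent variant appropriate for leads
        whose central-anode polarity inversion has not been corrected.

    Returns
    -------
    HeartVector
        ``Vh >= 0`` always; an all-zero input yields ``Vh=0, alpha=0`` with
        the ``degenerate`` flag set, since a calibrated rest state is a
        legitimate zero, not an error.
    """
    vx = t.DI
    vy = (t.DI + 2.0 * t.DIII) / _SQRT3
    if printed_signs:
        vy = -vy
    if vx == 0.0 and vy == 0.0:
        return HeartVector(Vh=0.0, alpha_deg=0.0, degenerate=True)
    return HeartVector(
        Vh=math.hypot(vx, vy),
        alpha_deg=_wrap_angle_deg(math.degrees(math.atan2(vy, vx))),
    )


def einthoven_residual(t: LeadTriplet) -> float:
    """Consistency diagnostic ``DII - DI - DIII`` (exactly 0 for any
    projection of a single dipole)."""
    return t.DII - t.DI - t.DIII


def loop_from_series(
    s: LeadSeries,
    printed_signs: bool = False,
    residual_tol_frac: float = 0.05,
) -> VCGLoop:
    """Trace the frontal VCG loop of a lead record, sample by sample.

    Emits an `EinthovenWarning` (without blocking) when the worst residual
    exceeds ``residual_tol_frac`` of the record's peak lead magnitude —
    expected for real ECG data, where the three leads are not an exact
    single-dipole projection.
    """
    n = len(s)
    vx = s.DI.copy()
    vy = (s.DI + 2.0 * s.DIII) / _SQRT3
    if printed_signs:
        vy = -vy
    Vh = np.hypot(vx, vy)
    degenerate = (vx == 0.0) & (vy == 0.0)
    alpha = np.degrees(np.arctan2(vy, vx))
    alpha[degenerate] = 0.0
    # wrap the +180 boundary down to -180
    alpha[alpha >= 180.0] -= 360.0
    residual = s.DII - s.DI - s.DIII

    peak = max(np.max(np.abs(s.DI)), np.max(np.abs(s.DII)), np.max(np.abs(s.DIII)))
    worst = float(np.max(np.abs(residual)))
    if peak > 0 and worst > residual_tol_frac * peak:
        warnings.warn(
            f"Einthoven residual up to {worst:.3g} V exceeds "
            f"{residual_tol_frac:.0%} of the peak lead magnitude {peak:.3g} V; "
            "the record is not an exact single-dipole projection",
            EinthovenWarning,
            stacklevel=2,
        )
    return VCGLoop(
        t=s.t, vx=vx, vy=vy, Vh=Vh, alpha_deg=alpha,
        residual=residual, degenerate=degenerate,
    )
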