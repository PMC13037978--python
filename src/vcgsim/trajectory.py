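"""Dipole trajectory generators and loop-parameter recovery.

Two trajectory families mirror how the teaching rig is validated:

* **Controlled circles** — the mobile source travels a circle of known
  radius and angular velocity; every lead then traces a sinusoid whose
  amplitude scales with the radius and whose frequency scales with the
  angular velocity, and the three leads sit 60 degrees apart in phase.
  This is the quantitative conformity check.

* **Parametric cardiac cycles** — a synthetic P-QRS-T sequence.  Each wave
  is traced as a closed teardrop loop that departs from and returns to the
  origin: with normalized phase ``s in [0, 1]`` over the wave duration,

      Vh(s)    = amplitude * sin(pi * s)
      alpha(s) = axis + direction * spread * cos(pi * s)

  so the vector sweeps from ``axis + spread`` to ``axis - spread`` while
  its magnitude rises and falls, passing through the mean axis exactly at
  peak magnitude.  Isoelectric segments (PR, ST, TP) hold the vector at
  the origin.  This parametrization is this package's own synthetic
  construction — smooth, closed, origin-anchored and oval-like — not a
  physiological model; defaults resemble textbook-normal values.

Time scales: ``real`` uses physiological durations (QRS ~ 85 ms); ``hand``
dilates every duration by a single multiplier (default 12.5), emulating a
manually traced loop that runs at roughly 1000-1500 ms per QRS instead of
70-100 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .forward import TankConfig, tank_leads
from .geometry import FrontalPoint
from .reconstruct import LeadSeries, VCGLoop

__all__ = [
    "CircularTrajectory",
    "WaveParams",
    "CardiacCycleParams",
    "gen_circular",
    "gen_cardiac_cycle",
    "add_noise",
    "beat_average",
    "peak_vector",
    "normal_cycle_params",
    "altered_cycle_params",
    "PRESETS",
]

_SQRT3 = math.sqrt(3.0)


# ---------------------------------------------------------------------------
# circular trajectories (conformity analysis)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularTrajectory:
    """A circle of ``radius_mm`` traversed at ``omega`` rad/s (sign = direction).

    ``gain_v_per_mm`` is the ideal-model scale between source displacement
    and heart-vector magnitude: a source ``r`` mm from the centre maps to a
    vector of ``gain * r`` volts.
    """

    radius_mm: float
    omega: float
    fs: float
    n_revolutions: float = 1.0
    center: FrontalPoint = field(default=FrontalPoint(0.0, 0.0))
    gain_v_per_mm: float = 0.01

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.omega == 0:
            raise ValueError("omega must be nonzero")
        if self.n_revolutions <= 0:
            raise ValueError("n_revolutions must be > 0")
        if self.fs <= abs(self.omega) / math.pi:  # Nyquist: fs > 2 * rotation freq
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist for rotation frequency "
                f"{abs(self.omega) / (2 * math.pi):.4g} Hz"
            )


def gen_circular(
    c: CircularTrajectory,
    model: Literal["ideal", "tank"] = "ideal",
    cfg: TankConfig | None = None,
) -> tuple[LeadSeries, np.ndarray]:
    """Render a circular trajectory to leads; also return the source path.

    Returns
    -------
    (LeadSeries, ndarray)
        The lead record and the ground-truth source positions, shape
        ``(n, 2)`` in millimetres.

    Notes
    -----
    Ideal model: ``DI(t) = g r cos(w t)``, ``DIII(t) = g r cos(w t - 120deg)``,
    ``DII = DI + DIII`` — three sinusoids 60 degrees apart in phase whose
    amplitude is proportional to the radius.  Tank model: the resistive
    point-source forward model is evaluated along the sampled circle.
    """
    duration = c.n_revolutions * 2.0 * math.pi / abs(c.omega)
    n = max(1, int(round(duration * c.fs)))
    t = np.arange(n) / c.fs
    phase = c.omega * t
    pos = np.stack(
        [c.center.x + c.radius_mm * np.cos(phase), c.center.y + c.radius_mm * np.sin(phase)],
        axis=1,
    )
    if model == "ideal":
        amp = c.gain_v_per_mm * c.radius_mm
        DI = amp * np.cos(phase)
        DIII = amp * np.cos(phase - np.deg2rad(120.0))
        series = LeadSeries(fs=c.fs, DI=DI, DII=DI + DIII, DIII=DIII)
    elif model == "tank":
        if cfg is None:
            cfg = TankConfig()
        triplets = [tank_leads(FrontalPoint(float(x), float(y)), cfg) for x, y in pos]
        series = LeadSeries(
            fs=c.fs,
            DI=np.array([tr.DI for tr in triplets]),
            DII=np.array([tr.DII for tr in triplets]),
            DIII=np.array([tr.DIII for tr in triplets]),
        )
    else:
        raise ValueError(f"unknown forward model {model!r}")
    return series, pos


# ---------------------------------------------------------------------------
# parametric cardiac cycles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveParams:
    """One wave's loop: peak magnitude (V), mean axis and opening half-angle
    (deg), and duration (s, real time scale)."""

    amplitude: float
    axis_deg: float
    spread_deg: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("wave amplitude must be >= 0")
        if self.duration_s < 0:
            raise ValueError("wave duration must be >= 0")


@dataclass(frozen=True)
class CardiacCycleParams:
    """Parameters of the synthetic P-QRS-T cycle.

    Defaults resemble textbook-normal frontal-plane values: amplitudes
    0.1/1.0/0.3 V, axes 50/60/45 deg, spreads 25/40/20 deg, durations
    90/85/180 ms, with PR/ST/TP isoelectric segments of 60/100/300 ms
    (cycle length 0.815 s, ~74 beats/min).  ``time_scale='hand'`` dilates
    every duration by ``hand_multiplier``.  ``loop_direction`` (+1/-1)
    sets the traversal sense; +1 (default) is counterclockwise in the
    y-inferior frontal convention.  ``qrs_dropped_every = k`` zeroes the
    QRS loop of every k-th cycle (a crude conduction-block preset).
    """

    P: WaveParams = field(default_factory=lambda: WaveParams(0.1, 50.0, 25.0, 0.090))
    QRS: WaveParams = field(default_factory=lambda: WaveParams(1.0, 60.0, 40.0, 0.085))
    T: WaveParams = field(default_factory=lambda: WaveParams(0.3, 45.0, 20.0, 0.180))
    pr_segment_s: float = 0.060
    st_segment_s: float = 0.100
    tp_segment_s: float = 0.300
    time_scale: Literal["real", "hand"] = "real"
    hand_multiplier: float = 12.5
    noise_sd: float = 0.0
    seed: int = 0
    loop_direction: int = 1
    qrs_dropped_every: int | None = None

    def __post_init__(self) -> None:
        for seg in (self.pr_segment_s, self.st_segment_s, self.tp_segment_s):
            if seg < 0:
                raise ValueError("segment durations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.loop_direction not in (-1, 1):
            raise ValueError("loop_direction must be +1 or -1")
        if self.qrs_dropped_every is not None and self.qrs_dropped_every < 1:
            raise ValueError("qrs_dropped_every must be >= 1")

    @property
    def scale(self) -> float:
        return self.hand_multiplier if self.time_scale == "hand" else 1.0

    @property
    def cycle_length_s(self) -> float:
        """Total cycle duration in seconds (at the selected time scale)."""
        return self.scale * (
            self.P.duration_s + self.pr_segment_s
            + self.QRS.duration_s + self.st_segment_s
            + self.T.duration_s + self.tp_segment_s
        )


def normal_cycle_params(time_scale: Literal["real", "hand"] = "real") -> CardiacCycleParams:
    """The default, textbook-normal-resembling synthetic cycle."""
    return CardiacCycleParams(time_scale=time_scale)


def altered_cycle_params(
    time_scale: Literal["real", "hand"] = "real",
    dropped_every: int = 3,
) -> CardiacCycleParams:
    """A conduction-block-like preset: every ``dropped_every``-th QRS loop is
    dropped (P waves march on).  Illustrative, not a clinical model."""
    return CardiacCycleParams(time_scale=time_scale, qrs_dropped_every=dropped_every)


PRESETS = {"normal": normal_cycle_params, "altered": altered_cycle_params}


def _cycle_truth(
    p: CardiacCycleParams, tau: np.ndarray, cycle_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (Vh, alpha_rad) at in-cycle times ``tau`` (seconds)."""
    k = p.scale
    Vh = np.zeros_like(tau)
    alpha = np.zeros_like(tau)
    start = 0.0
    for name, w, gap in (
        ("P", p.P, p.pr_segment_s),
        ("QRS", p.QRS, p.st_segment_s),
        ("T", p.T, p.tp_segment_s),
    ):
        dur = w.duration_s * k
        if dur > 0:
            m = (tau >= start) & (tau < start + dur)
            s = (tau[m] - start) / dur
            amp = np.full(m.sum(), w.amplitude)
            if name == "QRS" and p.qrs_dropped_every is not None:
                dropped = (cycle_index[m] + 1) % p.qrs_dropped_every == 0
                amp[dropped] = 0.0
            Vh[m] = amp * np.sin(np.pi * s)
            alpha[m] = np.deg2rad(
                w.axis_deg + p.loop_direction * w.spread_deg * np.cos(np.pi * s)
            )
        start += dur + gap * k
    return Vh, alpha


def gen_cardiac_cycle(
    p: CardiacCycleParams,
    n_cycles: int = 1,
    model: Literal["ideal", "tank"] = "ideal",
    cfg: TankConfig | None = None,
    fs: float = 800.0,
    gain_v_per_mm: float = 0.1,
) -> tuple[LeadSeries, VCGLoop]:
    """Render ``n_cycles`` synthetic cardiac cycles to leads.

    Returns the (possibly noisy) lead record and the exact noiseless
    ground-truth loop.  For the tank model the heart vector is mapped to a
    source displacement of ``Vh / gain_v_per_mm`` millimetres from the sink
    (default 0.1 V/mm keeps a 1 V QRS apex at 10 mm, inside the near-field
    region of the default 100 mm triangle); zero-magnitude samples emit
    zero leads directly, the dipole limit of a source at the sink.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    cyc = p.cycle_length_s
    if cyc <= 0:
        raise ValueError("cycle length must be positive")
    n = max(1, int(round(n_cycles * cyc * fs)))
    t = np.arange(n) / fs
    cycle_index = np.floor(t / cyc).astype(int)
    tau = t - cycle_index * cyc
    Vh, alpha = _cycle_truth(p, tau, cycle_index)

    vx = Vh * np.cos(alpha)
    vy = Vh * np.sin(alpha)
    truth = VCGLoop(
        t=t, vx=vx, vy=vy, Vh=Vh,
        alpha_deg=np.where(Vh > 0, np.degrees(alpha), 0.0),
        residual=np.zeros(n), degenerate=(Vh == 0.0),
    )

    if model == "ideal":
        DI = Vh * np.cos(alpha)
        DIII = Vh * np.cos(alpha - np.deg2rad(120.0))
        series = LeadSeries(fs=fs, DI=DI, DII=DI + DIII, DIII=DIII)
    elif model == "tank":
        if cfg is None:
            cfg = TankConfig()
        r_mm = Vh / gain_v_per_mm
        DI = np.zeros(n)
        DII = np.zeros(n)
        DIII = np.zeros(n)
        sink = cfg.sink
        for i in range(n):
            if r_mm[i] == 0.0:
                continue
            src = FrontalPoint(
                sink.x + r_mm[i] * math.cos(alpha[i]),
                sink.y + r_mm[i] * math.sin(alpha[i]),
            )
            tr = tank_leads(src, cfg)
            DI[i], DII[i], DIII[i] = tr.DI, tr.DII, tr.DIII
        series = LeadSeries(fs=fs, DI=DI, DII=DII, DIII=DIII)
    else:
        raise ValueError(f"unknown forward model {model!r}")

    if p.noise_sd > 0:
        series = add_noise(series, p.noise_sd, p.seed)
    return series, truth


def add_noise(s: LeadSeries, sd: float, seed: int) -> LeadSeries:
    """Add i.i.d. per-lead Gaussian noise; ``sd=0`` returns the input unchanged."""
    if sd < 0:
        raise ValueError(f"noise sd must be >= 0, got {sd}")
    if sd == 0:
        return s
    rng = np.random.default_rng(seed)
    return replace(
        s,
        DI=s.DI + rng.normal(0.0, sd, len(s)),
        DII=s.DII + rng.normal(0.0, sd, len(s)),
        DIII=s.DIII + rng.normal(0.0, sd, len(s)),
    )


# ---------------------------------------------------------------------------
# loop-parameter recovery
# ---------------------------------------------------------------------------

def beat_average(s: LeadSeries, cycle_length_s: float) -> LeadSeries:
    """Sample-wise average of consecutive cycles of known length.

    Classic signal averaging: with ``m`` complete cycles in the record the
    noise standard deviation drops by ``sqrt(m)`` while the deterministic
    beat is preserved.  Requires at least one complete cycle.
    """
    per = int(round(cycle_length_s * s.fs))
    if per < 1:
        raise ValueError("cycle length shorter than one sample")
    m = len(s) // per
    if m < 1:
        raise ValueError("record shorter than one cycle")
    def avg(x: np.ndarray) -> np.ndarray:
        return x[: m * per].reshape(m, per).mean(axis=0)
    return LeadSeries(fs=s.fs, DI=avg(s.DI), DII=avg(s.DII), DIII=avg(s.DIII), t0=s.t0)


def peak_vector(
    loop: VCGLoop,
    fs: float,
    smooth_window_s: float = 0.021,
    cap_frac: float = 0.8,
    fit_halfwidth_s: float = 0.016,
) -> tuple[float, float]:
    """Estimate the maximal heart vector of a loop: ``(Vh_peak, alpha_deg)``.

    Designed to stay accurate on noisy records:

    * the Cartesian components are smoothed with a moving average of
      ``smooth_window_s`` to locate the apex sample;
    * the peak *orientation* is the direction of the magnitude-weighted
      mean vector over the apex cap (smoothed magnitude >= ``cap_frac`` of
      its maximum).  For a loop symmetric about its axis this estimator is
      exact, and averaging over the cap suppresses noise far better than
      reading the angle at a single sample;
    * the peak *magnitude* is the apex of a quadratic fitted by least
      squares to the raw magnitude within ``fit_halfwidth_s`` of the apex
      sample, which avoids both the attenuation of the smoothed magnitude
      and single-sample noise.

    ``smooth_window_s`` and ``fit_halfwidth_s`` should stay well below the
    dominant wave's duration.
    """
    n = len(loop)
    if n == 0:
        raise ValueError("empty loop")
    w = max(1, int(round(smooth_window_s * fs)))
    kernel = np.ones(w) / w
    sx = np.convolve(loop.vx, kernel, mode="same")
    sy = np.convolve(loop.vy, kernel, mode="same")
    sV = np.hypot(sx, sy)
    i = int(np.argmax(sV))

    cap = sV >= cap_frac * sV[i]
    wgt = sV[cap]
    mx = float(np.sum(wgt * sx[cap]) / np.sum(wgt))
    my = float(np.sum(wgt * sy[cap]) / np.sum(wgt))
    alpha = math.degrees(math.atan2(my, mx))
    if alpha >= 180.0:
        alpha -= 360.0

    K = max(1, int(round(fit_halfwidth_s * fs)))
    lo, hi = max(0, i - K), min(n, i + K + 1)
    raw = np.hypot(loop.vx, loop.vy)
    if hi - lo >= 3:
        xs = np.arange(lo, hi, dtype=float) - i
        c = np.polyfit(xs, raw[lo:hi], 2)
        if c[0] < 0:
            vh = float(c[2] - c[1] ** 2 / (4.0 * c[0]))
        else:
            vh = float(raw[i])
    else:
        vh = float(raw[i])
    return vh, alpha
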