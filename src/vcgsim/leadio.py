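"""Lead-record file I/O and configuration loading.

The interchange format is a plain CSV dialect:

* header ``time_s,DI,DII,DIII`` (the ``DII`` column may be absent, in which
  case it is synthesized as ``DI + DIII`` with a warning — Einthoven's law
  makes it redundant);
* values in volts, ``.`` decimal separator, UTF-8;
* comment lines prefixed ``#``;
* time strictly increasing and uniformly sampled (checked to 1e-6 relative
  step jitter; non-uniform files are rejected unless resampling is allowed).

Full double precision survives a write/read round trip (17 significant
digits).  Digitized three-lead records from public ECG databases can be
converted to this dialect externally and fed straight to the
reconstruction pipeline, bypassing any physical acquisition.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forward import TankConfig
from .geometry import make_triangle
from .reconstruct import LeadSeries, VCGLoop

__all__ = [
    "read_leads_csv",
    "write_leads_csv",
    "write_loop_csv",
    "load_config",
    "tank_config_from_dict",
]

_REL_STEP_TOL = 1e-6


def read_leads_csv(path: str | Path, allow_resample: bool = False) -> LeadSeries:
    """Read a lead record from the CSV dialect above.

    Parameters
    ----------
    path : path-like
        Input file.
    allow_resample : bool
        When the time column is monotone but not uniform, linearly resample
        onto a uniform grid at the median step instead of rejecting.

    Raises
    ------
    ValueError
        Missing ``time_s``/``DI``/``DIII`` columns, non-monotone time, or
        non-uniform time with ``allow_resample=False``.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("time_s", "DI", "DIII") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer the sampling rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dt))
    fs = 1.0 / step
    DI = df["DI"].to_numpy(dtype=float)
    DIII = df["DIII"].to_numpy(dtype=float)
    if "DII" in df.columns:
        DII = df["DII"].to_numpy(dtype=float)
    else:
        warnings.warn(
            f"{path}: no DII column; synthesizing DII = DI + DIII (Einthoven's law)",
            UserWarning,
            stacklevel=2,
        )
        DII = DI + DIII

    jitter = float(np.max(np.abs(dt - step))) / step
    if jitter > _REL_STEP_TOL:
        if not allow_resample:
            raise ValueError(
                f"{path}: non-uniform sampling (relative step jitter {jitter:.3g}); "
                "pass allow_resample=True to interpolate onto a uniform grid"
            )
        n = int(round((t[-1] - t[0]) / step)) + 1
        tu = t[0] + np.arange(n) * step
        DI, DII, DIII = (np.interp(tu, t, x) for x in (DI, DII, DIII))
        t = tu
    return LeadSeries(fs=fs, DI=DI, DII=DII, DIII=DIII, t0=float(t[0]))


def write_leads_csv(s: LeadSeries, path: str | Path) -> None:
    """Write a lead record in the CSV dialect (17 significant digits)."""
    if len(s) == 0:
        raise ValueError("cannot write an empty lead series")
    t = s.t
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,DI,DII,DIII\n")
        for i in range(len(s)):
            fh.write(
                f"{t[i]:.17g},{s.DI[i]:.17g},{s.DII[i]:.17g},{s.DIII[i]:.17g}\n"
            )


def write_loop_csv(loop: VCGLoop, path: str | Path) -> None:
    """Write a reconstructed loop: ``t_s,vx_V,vy_V,Vh_V,alpha_deg,residual_V``."""
    if len(loop) == 0:
        raise ValueError("cannot write an empty loop")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("t_s,vx_V,vy_V,Vh_V,alpha_deg,residual_V\n")
        for i in range(len(loop)):
            fh.write(
                f"{loop.t[i]:.17g},{loop.vx[i]:.17g},{loop.vy[i]:.17g},"
                f"{loop.Vh[i]:.17g},{loop.alpha_deg[i]:.17g},{loop.residual[i]:.17g}\n"
            )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def tank_config_from_dict(d: dict) -> tuple[TankConfig, str]:
    """Build a `TankConfig` (and the selected forward model name) from config keys.

    Recognized keys: ``side_length_mm`` (default 100), ``sigma_S_per_m``
    (default 1.5), ``source_current_A`` (default 1e-3),
    ``polarity_inverted`` (default true), ``model`` (``ideal`` | ``tank``,
    default ``ideal``).
    """
    model = str(d.get("model", "ideal"))
    if model not in ("ideal", "tank"):
        raise ValueError(f"config: unknown model {model!r} (expected 'ideal' or 'tank')")
    cfg = TankConfig(
        triangle=make_triangle(float(d.get("side_length_mm", 100.0))),
        conductivity=float(d.get("sigma_S_per_m", 1.5)),
        source_current=float(d.get("source_current_A", 1e-3)),
        polarity_inverted=bool(d.get("polarity_inverted", True)),
    )
    return cfg, model
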