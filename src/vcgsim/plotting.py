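"""Static rendering of lead waveforms and frontal VCG loops.

The panel layout mirrors the didactic display of the teaching rig: three
stacked lead traces on the left, the Einthoven triangle with the traced
loop on the right.  The y axis of the loop panel is flipped so that the
y-inferior data convention renders in the familiar clinical orientation
(superior up).  Rendering is best-effort plumbing, not a tested contract
beyond "a file is produced".
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .geometry import TriangleConfig, make_triangle
from .reconstruct import LeadSeries, VCGLoop

__all__ = ["plot_record"]


def plot_record(
    series: LeadSeries,
    loop: VCGLoop | None,
    path: str | Path,
    triangle: TriangleConfig | None = None,
    title: str | None = None,
) -> None:
    """Render a record (and optionally its loop) to an image file."""
    if loop is not None:
        fig, (ax_leads, ax_loop) = plt.subplots(
            1, 2, figsize=(11, 4.5), gridspec_kw={"width_ratios": [1.4, 1]}
        )
    else:
        fig, ax_leads = plt.subplots(figsize=(8, 4.5))
        ax_loop = None

    t = series.t
    offsets = 0.0
    span = max(
        series.DI.max() - series.DI.min(),
        series.DII.max() - series.DII.min(),
        series.DIII.max() - series.DIII.min(),
        1e-12,
    )
    for name, trace in (("DI", series.DI), ("DII", series.DII), ("DIII", series.DIII)):
        ax_leads.plot(t, trace + offsets, lw=0.9, label=name)
        offsets -= 1.3 * span
    ax_leads.set_xlabel("time (s)")
    ax_leads.set_ylabel("lead voltage (V, stacked)")
    ax_leads.legend(loc="upper right", fontsize=8)
    ax_leads.set_title("Leads DI / DII / DIII")

    if ax_loop is not None:
        tri = triangle or make_triangle()
        scale = max(loop.Vh.max(), 1e-12)
        # triangle drawn in vector units so both fit one frame
        k = 1.2 * scale / (tri.side_length / 1.7320508075688772)
        verts = [tri.vertex_RA, tri.vertex_LA, tri.vertex_LL, tri.vertex_RA]
        ax_loop.plot(
            [v.x * k for v in verts], [v.y * k for v in verts],
            color="0.6", lw=1.0,
        )
        for name, v in tri.vertices.items():
            ax_loop.annotate(name, (v.x * k, v.y * k), fontsize=8, color="0.4")
        ax_loop.plot(loop.vx, loop.vy, lw=0.8, color="tab:red")
        ax_loop.set_aspect("equal")
        ax_loop.invert_yaxis()  # y-inferior data, clinical display
        ax_loop.set_xlabel("vx (V)")
        ax_loop.set_ylabel("vy (V, inferior down)")
        ax_loop.set_title("Frontal VCG loop")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
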