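"""Static score-card rendering: plain text and SVG.

Each main effect is drawn as a strip of interval cells with thresholds at
the boundaries and the integer points inside; interactions are drawn as
grids.  A final strip maps every achievable total score to its risk.  Cell
colours come from a diverging map centered at 0 points, shared across all
effects so equal points always get equal colours; the grayscale variant
maps the point magnitude instead.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .pipeline import ScoreModel


def _point_color(points: int, vmax: int, grayscale: bool) -> str:
    if vmax == 0:
        frac = 0.5
    elif grayscale:
        # magnitude map: 0 points -> white, max |points| -> dark
        return to_hex((1 - 0.8 * abs(points) / vmax,) * 3)
    else:
        frac = 0.5 + 0.5 * points / vmax
    return to_hex(colormaps["RdBu_r"](frac))


def render_scorecard(model: ScoreModel, format: str = "txt",
                     grayscale: bool = False) -> str:
    """Render a fitted model as a text block or an SVG document."""
    if format == "txt":
        return _render_txt(model)
    if format == "svg":
        return _render_svg(model, grayscale)
    raise ValueError(f"unknown format {format!r}; use 'txt' or 'svg'")


def _render_txt(model: ScoreModel) -> str:
    lines = ["=== Interval coded scorecard ==="]
    for e in model.effects:
        if e.kind == "main":
            labels = e.margins[0].interval_labels()
            cells = " | ".join(
                f"{lab}: {int(p):+d}" for lab, p in zip(labels, e.points)
            )
            lines.append(f"{e.name}:  {cells}")
        else:
            lines.append(f"{e.name} (interaction):")
            row_labs = e.margins[0].interval_labels()
            col_labs = e.margins[1].interval_labels()
            lines.append("    " + " | ".join(col_labs))
            for k, rl in enumerate(row_labs):
                row = " | ".join(f"{int(p):+d}" for p in e.points[k])
                lines.append(f"  {rl}:  {row}")
    lines.append("--- risk profile ---")
    for s in sorted(model.risk_table):
        lines.append(f"score {s:+d}: risk {model.risk_table[s] * 100:.1f}%")
    lines.append(
        f"target class: label {model.label_map['positive']:g} "
        f"(vs {model.label_map['negative']:g})"
    )
    return "\n".join(lines)


def _render_svg(model: ScoreModel, grayscale: bool) -> str:
    cell_w, cell_h, pad, label_h = 80, 36, 14, 16
    vmax = max(
        [int(np.abs(np.asarray(e.points)).max()) for e in model.effects],
        default=0,
    )
    parts = []
    y = pad

    def text(x, yy, s, size=11, anchor="middle"):
        parts.append(
            f'<text x="{x}" y="{yy}" font-size="{size}" '
            f'text-anchor="{anchor}" font-family="sans-serif">{s}</text>'
        )

    width = 2 * pad
    for e in model.effects:
        text(pad, y + 12, e.name, size=12, anchor="start")
        y += label_h
        if e.kind == "main":
            vb = e.margins[0]
            labels = vb.interval_labels()
            for k, p in enumerate(e.points):
                x = pad + k * cell_w
                fill = _point_color(int(p), vmax, grayscale)
                parts.append(
                    f'<rect x="{x}" y="{y}" width="{cell_w}" height="{cell_h}" '
                    f'fill="{fill}" stroke="black"/>'
                )
                text(x + cell_w / 2, y + cell_h / 2 + 4, f"{int(p):+d}")
            # thresholds at interior boundaries
            for k, tau in enumerate(np.asarray(vb.thresholds)):
                x = pad + (k + 1) * cell_w
                text(x, y + cell_h + 12, f"{tau:.4g}", size=10)
            # level labels for binary/categorical
            if vb.levels is not None:
                for k, lab in enumerate(labels):
                    text(pad + k * cell_w + cell_w / 2, y + cell_h + 12, lab, size=10)
            width = max(width, 2 * pad + len(e.points) * cell_w)
            y += cell_h + label_h + pad
        else:
            n1, n2 = e.points.shape
            for k in range(n1):
                for l in range(n2):
                    x = pad + l * cell_w
                    yy = y + k * cell_h
                    fill = _point_color(int(e.points[k, l]), vmax, grayscale)
                    parts.append(
                        f'<rect x="{x}" y="{yy}" width="{cell_w}" '
                        f'height="{cell_h}" fill="{fill}" stroke="black"/>'
                    )
                    text(x + cell_w / 2, yy + cell_h / 2 + 4,
                         f"{int(e.points[k, l]):+d}")
            width = max(width, 2 * pad + n2 * cell_w)
            y += n1 * cell_h + label_h + pad

    # risk strip
    text(pad, y + 12, "risk profile", size=12, anchor="start")
    y += label_h
    scores = sorted(model.risk_table)
    rw = max(40, int(cell_w * 0.6))
    for i, s in enumerate(scores):
        x = pad + i * rw
        risk = model.risk_table[s]
        fill = to_hex((1 - 0.6 * risk,) * 3) if grayscale else to_hex(
            colormaps["RdBu_r"](0.5 + 0.5 * (2 * risk - 1))
        )
        parts.append(
            f'<rect x="{x}" y="{y}" width="{rw}" height="{cell_h}" '
            f'fill="{fill}" stroke="black"/>'
        )
        text(x + rw / 2, y + 14, f"{s:+d}", size=10)
        text(x + rw / 2, y + 28, f"{risk * 100:.0f}%", size=10)
    width = max(width, 2 * pad + len(scores) * rw)
    y += cell_h + pad

    header = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{y}" viewBox="0 0 {width} {y}">'
    )
    return "\n".join([header, *parts, "</svg>"])
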