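"""Ternary-plot geometry and rendering for evidence triples.

An evidence triple (alpha, beta, theta) sums to one, so all triples lie in a
plane; the isometric (orthographic) projection of that plane is the ternary
plot.  Corner convention, fixed and not configurable so that plots remain
comparable: beta = 1 at the lower-left corner (0, 0), alpha = 1 at the
lower-right corner (1, 0), theta = 1 at the apex (1/2, sqrt(3)/2).

    x = alpha + theta / 2
    y = theta * sqrt(3) / 2

Decision borders alpha = t and beta = t project to straight segments; the
triangle partitions into a positive triangle (alpha > t), a negative
triangle (beta > t), and the inconclusive kite between them.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Sequence

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Polygon

from .evidence import Call, Evidence, classify

__all__ = [
    "SQRT3_2",
    "TernaryPoint",
    "project",
    "project_many",
    "region_of",
    "region_polygons",
    "render",
    "coordinates_frame",
    "unproject",
]

SQRT3_2 = math.sqrt(3.0) / 2.0


class TernaryPoint(NamedTuple):
    x: float
    y: float


def project(e: Evidence) -> TernaryPoint:
    """Map an evidence triple to planar coordinates (injective)."""
    return TernaryPoint(e.alpha + e.theta / 2.0, e.theta * SQRT3_2)


def project_many(evidences: Iterable[Evidence]) -> np.ndarray:
    """(n, 2) array of projected coordinates."""
    return np.array([project(e) for e in evidences], dtype=float).reshape(-1, 2)


def unproject(p, tol: float = 1e-9) -> Evidence:
    """Exact inverse of :func:`project`; rejects points outside the triangle."""
    x, y = float(p[0]), float(p[1])
    theta = y / SQRT3_2
    alpha = x - theta / 2.0
    beta = 1.0 - alpha - theta
    for m in (alpha, beta, theta):
        if m < -tol:
            raise ValueError(f"point ({x}, {y}) lies outside the ternary triangle")
    return Evidence(max(alpha, 0.0), max(beta, 0.0), max(theta, 0.0))


def region_of(e: Evidence, threshold: float = 0.5) -> Call:
    """Geometric region of a triple; identical to the algebraic decision."""
    return classify(e, threshold)


def region_polygons(threshold: float = 0.5) -> dict[Call, np.ndarray]:
    """Vertices (plot coordinates) of the three decision regions.

    Positive triangle: alpha > t; negative triangle: beta > t; the
    inconclusive kite is the remainder of the simplex.
    """
    t = float(threshold)
    pos = project_many(
        [Evidence(1, 0, 0), Evidence(t, 1 - t, 0), Evidence(t, 0, 1 - t)]
    )
    neg = project_many(
        [Evidence(0, 1, 0), Evidence(1 - t, t, 0), Evidence(0, t, 1 - t)]
    )
    kite = project_many(
        [
            Evidence(t, 1 - t, 0),
            Evidence(t, 0, 1 - t),
            Evidence(0, 0, 1),
            Evidence(0, t, 1 - t),
            Evidence(1 - t, t, 0),
        ]
    )
    return {Call.POS: pos, Call.NEG: neg, Call.INC: kite}


_REGION_FACE = {Call.POS: "#f6c6c6", Call.NEG: "#c6d4f6", Call.INC: "white"}
_DEFAULT_COLORS = {
    "pos": "#c22222",
    "neg": "#2244bb",
    "inc": "#c9a227",
}


def coordinates_frame(
    points: Sequence[tuple[Evidence, str, bool]]
) -> pd.DataFrame:
    """Projected coordinates + labels for export alongside a figure."""
    rows = []
    for e, color_label, open_marker in points:
        x, y = project(e)
        rows.append(
            {
                "alpha": e.alpha,
                "beta": e.beta,
                "theta": e.theta,
                "x": x,
                "y": y,
                "color_label": color_label,
                "open_marker": bool(open_marker),
                "region": region_of(e).value,
            }
        )
    return pd.DataFrame(rows)


def render(
    points: Sequence[tuple[Evidence, str, bool]],
    out_path,
    threshold: float = 0.5,
    title: str | None = None,
    colors: dict[str, str] | None = None,
) -> None:
    """Draw the ternary plot with decision regions and dual-coded samples.

    Each point is ``(evidence, color_label, open_marker)``: position encodes
    the fused evidence (and hence the fusion call, via the shaded region it
    falls in), color encodes a second classifier's label, and open circles
    flag samples with unknown IHC.
    """
    if len(points) == 0:
        raise ValueError("no points to plot")
    palette = dict(_DEFAULT_COLORS)
    if colors:
        palette.update(colors)

    fig, ax = plt.subplots(figsize=(6.5, 6.0))
    for call, verts in region_polygons(threshold).items():
        ax.add_patch(
            Polygon(verts, closed=True, facecolor=_REGION_FACE[call], zorder=0)
        )
    # triangle outline and the two decision borders
    tri = project_many([Evidence(0, 1, 0), Evidence(1, 0, 0), Evidence(0, 0, 1)])
    ax.add_patch(Polygon(tri, closed=True, fill=False, edgecolor="black", lw=1.2))
    t = threshold
    for a, b in (
        (project(Evidence(t, 1 - t, 0)), project(Evidence(t, 0, 1 - t))),
        (project(Evidence(1 - t, t, 0)), project(Evidence(0, t, 1 - t))),
    ):
        ax.plot([a.x, b.x], [a.y, b.y], ls="--", color="0.3", lw=1.0, zorder=1)

    seen_labels = []
    for e, color_label, open_marker in points:
        x, y = project(e)
        color = palette.get(str(color_label), "0.4")
        label = str(color_label) if color_label not in seen_labels else None
        if label:
            seen_labels.append(color_label)
        if open_marker:
            ax.scatter(
                x, y, s=28, facecolors="none", edgecolors=color, lw=1.2,
                zorder=2, label=label,
            )
        else:
            ax.scatter(x, y, s=22, color=color, zorder=2, label=label)

    for text, e, dy in (
        (r"$\beta=1$", Evidence(0, 1, 0), -0.04),
        (r"$\alpha=1$", Evidence(1, 0, 0), -0.04),
        (r"$\theta=1$", Evidence(0, 0, 1), 0.03),
    ):
        p = project(e)
        ax.text(p.x, p.y + dy, text, ha="center", fontsize=11)

    ax.set_xlim(-0.08, 1.08)
    ax.set_ylim(-0.10, SQRT3_2 + 0.10)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    if seen_labels:
        ax.legend(loc="upper right", frameon=False, fontsize=9)
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
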