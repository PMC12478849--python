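"""Short- vs long-distance classification of propeller loops.

A propeller loop bridges the bottom tetrad of one G-tract and the top
tetrad of the next.  Because the stacked tetrads are twisted by the helix,
the two backbone attachment points can end up azimuthally close
(short-distance, SD) or far apart (long-distance, LD), depending on the
loop's winding direction, the running direction of the tract it leaves,
and the helicity.  LD propellers must span a much longer path around the
core and are strongly destabilizing.

Two independent classifiers are provided:

* :func:`classify_propellers_rule` -- the closed-form counting rule: under
  right-handed (RH) helicity a ``+p`` loop is long-distance iff 0 or 2
  non-propeller loops precede it in the sequence, a ``-p`` loop iff exactly
  1 precedes it; left-handed (LH) helicity swaps LD and SD.
* :func:`classify_propellers_geometric` -- measures, in a 2D "unwrap" of
  the core cylinder (:func:`unwrap_projection`), the in-plane distance a
  propeller traverses between its attachment points, respecting the loop's
  mandated winding direction, and thresholds it.

The two agree on all 26 topologies x 2 helicities; the counting rule is
treated as normative and the unwrap as a geometric consistency check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .topology import (
    Helicity,
    LoopType,
    Topology,
    enumerate_topologies,
    trace_topology,
)

__all__ = [
    "PropellerGeometry",
    "Projection2D",
    "classify_propellers_rule",
    "unwrap_projection",
    "classify_propellers_geometric",
    "count_long_distance",
    "census",
    "ld_threshold_band",
    "DEFAULT_TRACT_SPACING",
    "DEFAULT_TILT",
    "DEFAULT_LD_THRESHOLD",
    "projection_to_svg",
]

Label = Literal["SD", "LD", "NA"]
PropellerGeometry = tuple[Label, Label, Label]

#: Horizontal spacing between adjacent tract columns in the unwrapped plane
#: (arbitrary layout unit; only the SD/LD separation matters).
DEFAULT_TRACT_SPACING = 1.0
#: Horizontal displacement of the top of each tract column relative to its
#: bottom, in tract-spacing units; encodes the helical twist in the plane.
DEFAULT_TILT = 0.35
#: Tract column height in the unwrapped plane.
_TRACT_HEIGHT = 1.0


def _helicity_sign(helicity: Helicity) -> int:
    if helicity == "RH":
        return 1
    if helicity == "LH":
        return -1
    raise ValueError(f"helicity must be 'RH' or 'LH', got {helicity!r}")


def classify_propellers_rule(
    topology: Topology, helicity: Helicity = "RH"
) -> PropellerGeometry:
    """Label each loop position SD/LD/NA by the closed-form counting rule."""
    sigma = _helicity_sign(helicity)
    labels: list[Label] = []
    n_nonprop = 0
    for lt in topology.loops:
        if not lt.is_propeller:
            labels.append("NA")
            n_nonprop += 1
            continue
        if lt.sign > 0:
            ld = n_nonprop in (0, 2)
        else:
            ld = n_nonprop == 1
        if sigma < 0:
            ld = not ld
        labels.append("LD" if ld else "SD")
    return tuple(labels)  # type: ignore[return-value]


@dataclass(frozen=True)
class Projection2D:
    """Unwrapped (cut-and-flattened cylinder) 2D projection of a topology.

    Tracts appear left-to-right in strand order as tilted columns; each
    loop stores the pair of 2D attachment points its backbone connects.
    For a loop that winds against the unwrap direction, the second point
    is the periodic image reached by travelling the loop's own mandated
    winding direction, so the in-plane distance between the pair equals
    the unrolled length of the loop's traversal.
    """

    topology: Topology
    helicity: Helicity
    #: per-tract parallelogram corners, shape (4, 2): bottom-left,
    #: bottom-right, top-right, top-left.
    tracts: tuple[np.ndarray, ...]
    #: per-loop ((x1, y1), (x2, y2)) attachment pairs; lateral/diagonal
    #: loops get the anchor pair used only for drawing.
    attachments: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    unwrap_direction: Literal["clockwise", "counterclockwise"]
    five_prime_side: Literal["left", "right"]
    spacing: float
    tilt: float

    def attachment_distance(self, position: int) -> float:
        (x1, y1), (x2, y2) = self.attachments[position]
        return math.hypot(x2 - x1, y2 - y1)


def _first_signed_sign(topology: Topology) -> int:
    for lt in topology.loops:
        if lt.sign != 0:
            return lt.sign
    # Unreachable for valid topologies (an all-diagonal walk revisits
    # corners); default to anticlockwise unwrap.
    return -1


def unwrap_projection(
    topology: Topology,
    helicity: Helicity = "RH",
    spacing: float = DEFAULT_TRACT_SPACING,
    tilt: float = DEFAULT_TILT,
) -> Projection2D:
    """Unroll the core cylinder into a plane, following the strand.

    The unwrap direction follows the first (signed) loop: clockwise for a
    ``-`` first loop, counterclockwise for ``+``, which places the 5' end
    on the left or right edge of the projection respectively.  Tract
    columns are tilted by the in-plane image of the helical twist, whose
    sign is the product of helicity and unwrap direction; switching
    helicity therefore mirrors the projection about the vertical axis.
    """
    sigma = _helicity_sign(helicity)
    trace = trace_topology(topology.loops)
    s_first = _first_signed_sign(topology)
    # Unroll coordinate: x increases along the strand's initial winding
    # direction.  u maps azimuth to x so that strand order reads
    # left-to-right; the in-plane tilt is the twist as seen in that frame.
    u = -s_first
    tau = u * sigma * tilt * spacing  # top-of-column displacement

    width = 0.18 * spacing
    tracts = []
    for j in range(4):
        x = j * spacing
        tracts.append(
            np.array(
                [
                    [x - width / 2, 0.0],
                    [x + width / 2, 0.0],
                    [x + width / 2 + tau, _TRACT_HEIGHT],
                    [x - width / 2 + tau, _TRACT_HEIGHT],
                ]
            )
        )

    dirs = [1 if d == "up" else -1 for d in trace.directions]
    attachments = []
    for k, lt in enumerate(topology.loops):
        d_k = dirs[k]
        # exit anchor of tract k
        exit_top = d_k == 1
        x1 = k * spacing + (tau if exit_top else 0.0)
        y1 = _TRACT_HEIGHT if exit_top else 0.0
        if lt.is_propeller:
            # Winding-aware endpoint: horizontal span = spacing*(1 + w*tilt)
            # travelled in the loop's own direction; w = +1 marks the
            # long-distance geometry.
            w = lt.sign * d_k * sigma
            h = spacing * (1.0 + w * tilt)
            g = -u * lt.sign  # loop's direction in the plane frame
            x2 = x1 + g * h
            y2 = 0.0 if exit_top else _TRACT_HEIGHT
        else:
            # same-face connection; drawn to the entry anchor of the next
            # tract (diagonal skips one column in azimuth but is laid out
            # at the strand-order neighbour) -- drawing only, label is NA.
            x2 = (k + 1) * spacing + (tau if exit_top else 0.0)
            y2 = y1
        attachments.append(((x1, y1), (float(x2), float(y2))))

    return Projection2D(
        topology=topology,
        helicity=helicity,
        tracts=tuple(tracts),
        attachments=tuple(attachments),
        unwrap_direction="clockwise" if s_first < 0 else "counterclockwise",
        five_prime_side="left" if s_first < 0 else "right",
        spacing=spacing,
        tilt=tilt,
    )


def ld_threshold_band(
    spacing: float = DEFAULT_TRACT_SPACING, tilt: float = DEFAULT_TILT
) -> tuple[float, float]:
    """(max SD, min LD) in-plane attachment distances over all 52
    (topology, helicity) cases at the given layout constants.

    Any threshold strictly inside this band makes the geometric classifier
    coincide with the counting rule.
    """
    sd_max, ld_min = 0.0, math.inf
    for helicity in ("RH", "LH"):
        for topo in enumerate_topologies():
            proj = unwrap_projection(topo, helicity, spacing=spacing, tilt=tilt)
            labels = classify_propellers_rule(topo, helicity)
            for k, lab in enumerate(labels):
                if lab == "NA":
                    continue
                dist = proj.attachment_distance(k)
                if lab == "SD":
                    sd_max = max(sd_max, dist)
                else:
                    ld_min = min(ld_min, dist)
    return sd_max, ld_min


def _default_threshold() -> float:
    lo, hi = ld_threshold_band()
    return 0.5 * (lo + hi)


#: Midpoint of the admissible band at default layout constants
#: (hypot(1 - tilt, 1), hypot(1 + tilt, 1)) in spacing units.
DEFAULT_LD_THRESHOLD = _default_threshold()


def classify_propellers_geometric(
    projection: Projection2D, threshold: float = DEFAULT_LD_THRESHOLD
) -> PropellerGeometry:
    """Label propellers LD iff their in-plane attachment distance exceeds
    ``threshold``; non-propeller positions are NA."""
    labels: list[Label] = []
    for k, lt in enumerate(projection.topology.loops):
        if not lt.is_propeller:
            labels.append("NA")
        else:
            labels.append(
                "LD" if projection.attachment_distance(k) > threshold else "SD"
            )
    return tuple(labels)  # type: ignore[return-value]


def count_long_distance(topology: Topology, helicity: Helicity = "RH") -> int:
    """Number of long-distance propeller loops in the topology."""
    return sum(
        1 for lab in classify_propellers_rule(topology, helicity) if lab == "LD"
    )


def census(helicity: Helicity = "RH") -> pd.DataFrame:
    """Per-topology LD census at one helicity.

    Columns: topology, helicity, geometry_I..III, ld_count, has_ld.
    Under either helicity, 12 of the 26 topologies carry at least one
    long-distance propeller and 14 carry none.
    """
    rows = []
    for topo in enumerate_topologies():
        labels = classify_propellers_rule(topo, helicity)
        n_ld = sum(1 for lab in labels if lab == "LD")
        rows.append(
            {
                "topology": str(topo),
                "helicity": helicity,
                "geometry_I": labels[0],
                "geometry_II": labels[1],
                "geometry_III": labels[2],
                "ld_count": n_ld,
                "has_ld": n_ld > 0,
            }
        )
    return pd.DataFrame(rows)


def projection_to_svg(projection: Projection2D, path: str) -> None:
    """Write a minimal schematic SVG of the unwrapped projection.

    Layout plumbing only: tract parallelograms, loop connectors (LD
    propellers in red, everything else green) and a 5'-end marker.
    """
    scale, pad = 80.0, 40.0
    pts = np.vstack([t for t in projection.tracts])
    xs = [p for pair in projection.attachments for p in pair]
    pts = np.vstack([pts, np.array(xs)])
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)

    def tr(x: float, y: float) -> tuple[float, float]:
        return pad + (x - xmin) * scale, pad + (ymax - y) * scale

    w = 2 * pad + (xmax - xmin) * scale
    h = 2 * pad + (ymax - ymin) * scale
    labels = classify_propellers_rule(projection.topology, projection.helicity)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}">'
    ]
    for tract in projection.tracts:
        corner_str = " ".join(f"{tr(x, y)[0]:.1f},{tr(x, y)[1]:.1f}" for x, y in tract)
        parts.append(
            f'<polygon points="{corner_str}" fill="#cccccc" stroke="#555555"/>'
        )
    for k, ((x1, y1), (x2, y2)) in enumerate(projection.attachments):
        color = "#cc2222" if labels[k] == "LD" else "#22aa44"
        (ax, ay), (bx, by) = tr(x1, y1), tr(x2, y2)
        parts.append(
            f'<line x1="{ax:.1f}" y1="{ay:.1f}" x2="{bx:.1f}" y2="{by:.1f}" '
            f'stroke="{color}" stroke-width="3"/>'
        )
    # 5' marker at the base of the first tract
    cx, cy = tr(0.0, 0.0)
    parts.append(f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="6" fill="white" stroke="black"/>')
    parts.append(
        f'<text x="{pad / 4:.0f}" y="{h / 2:.0f}">'
        f"{projection.topology} {projection.helicity} 5'-{projection.five_prime_side}</text>"
    )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
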