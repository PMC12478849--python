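"""Idealized 3D G-core scaffolds, surface paths and superposition RMSD.

The scaffold places one backbone anchor (the loop attachment point,
standing in for the C4'/C3' atoms) per G-tract and tetrad level on a
cylinder: four tracts at 90 deg azimuthal spacing, successive tetrad
levels separated by the helical rise and rotated by the signed twist.
A propeller loop connecting two anchors must travel around the core in
its mandated winding direction; its shortest admissible route is modelled
as a geodesic on a guard cylinder slightly wider than the anchor radius.
On this idealized geometry the long-distance (LD) and short-distance (SD)
propeller paths form two cleanly separated length populations, mirroring
the two populations seen in folded all-atom structures (absolute lengths
are not comparable to ensemble averages and are not meant to be).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import classify_propellers_rule
from .topology import Helicity, LoopType, Topology, TopologyTrace, enumerate_topologies

__all__ = [
    "ScaffoldParams",
    "Scaffold",
    "SurfacePath",
    "build_scaffold",
    "loop_attachment_pair",
    "shortest_surface_path",
    "propeller_path_table",
    "kabsch_rmsd",
    "write_scaffold_pdb",
]

_ROMAN = {"I": 0, "II": 1, "III": 2}


@dataclass(frozen=True)
class ScaffoldParams:
    """Geometry of the idealized core.

    rise_nm
        Stacking rise per tetrad level (canonical nucleic-acid value).
    twist_deg
        Twist magnitude per tetrad level; sign is set by helicity.
    radius_nm
        Anchor radius: half-diagonal of the tetrad square.
    probe_nm
        Offset added to the anchor radius to form the guard cylinder on
        which loop paths run.
    """

    rise_nm: float = 0.34
    twist_deg: float = 30.0
    radius_nm: float = 1.0
    probe_nm: float = 0.2

    def __post_init__(self) -> None:
        if self.rise_nm <= 0 or self.radius_nm <= 0 or self.twist_deg <= 0:
            raise ValueError(f"geometry parameters must be positive: {self}")
        if self.probe_nm < 0:
            raise ValueError("probe_nm must be nonnegative")


@dataclass(frozen=True)
class Scaffold:
    """Anchor coordinates of an idealized G-core.

    ``anchors[c, L]`` is the xyz (nm) of the anchor at square corner ``c``
    (0-3, clockwise viewed from the top) and tetrad level ``L`` (0 =
    bottom).  Corner c sits at azimuth -90*c deg, shifted by the signed
    twist at each level; z = L * rise.
    """

    n_tetrads: int
    helicity: Helicity
    params: ScaffoldParams
    anchors: np.ndarray  # shape (4, n_tetrads, 3)

    def anchor(self, corner: int, level: int) -> np.ndarray:
        return self.anchors[corner % 4, level]


def build_scaffold(
    n_tetrads: int,
    helicity: Helicity = "RH",
    params: ScaffoldParams = ScaffoldParams(),
) -> Scaffold:
    """Deterministic anchor coordinates for a 2- or 3-tetrad core.

    Right-handed helicity rotates successive levels counterclockwise
    (viewed from the top, i.e. positive mathematical angle); left-handed
    mirrors the scaffold through a vertical plane.
    """
    if n_tetrads not in (2, 3):
        raise ValueError(f"n_tetrads must be 2 or 3, got {n_tetrads}")
    sigma = {"RH": 1, "LH": -1}.get(helicity)
    if sigma is None:
        raise ValueError(f"helicity must be 'RH' or 'LH', got {helicity!r}")
    anchors = np.empty((4, n_tetrads, 3))
    for c in range(4):
        for level in range(n_tetrads):
            theta = math.radians(-90.0 * c + sigma * params.twist_deg * level)
            anchors[c, level] = (
                params.radius_nm * math.cos(theta),
                params.radius_nm * math.sin(theta),
                params.rise_nm * level,
            )
    return Scaffold(n_tetrads=n_tetrads, helicity=helicity, params=params, anchors=anchors)


def loop_attachment_pair(
    scaffold: Scaffold, trace: TopologyTrace, position: int | str,
    loops: Sequence[LoopType] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Attachment anchors of the propeller loop at ``position`` (0-2 or
    Roman 'I'/'II'/'III').

    Returns the exit anchor of tract k (at its exit tetrad level) and the
    entry anchor of tract k+1 at the opposite level.  Raises ``ValueError``
    if the loop at that position is lateral or diagonal (their faces are
    recorded in the trace).
    """
    k = _ROMAN[position] if isinstance(position, str) else int(position)
    if not 0 <= k <= 2:
        raise ValueError(f"position must be 0-2 or I/II/III, got {position!r}")
    if trace.loop_faces[k] != "spanning":
        raise ValueError(
            f"loop at position {position} is not a propeller "
            f"(face={trace.loop_faces[k]})"
        )
    top = scaffold.n_tetrads - 1
    exit_level = top if trace.directions[k] == "up" else 0
    entry_level = top - exit_level
    a = scaffold.anchor(trace.corners[k], exit_level)
    b = scaffold.anchor(trace.corners[k + 1], entry_level)
    return a, b


@dataclass(frozen=True)
class SurfacePath:
    """Geodesic on the guard cylinder between two attachment points."""

    points: np.ndarray  # polyline vertices, shape (m, 3)
    length_nm: float
    winding: str  # "clockwise" | "counterclockwise"

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


def shortest_surface_path(
    scaffold: Scaffold,
    a: np.ndarray,
    b: np.ndarray,
    winding: str = "counterclockwise",
    n_segments: int = 32,
) -> SurfacePath:
    """Single-winding geodesic between ``a`` and ``b`` on the guard
    cylinder (radius = anchor radius + probe).

    The azimuthal span is taken strictly in ``winding`` direction
    (clockwise = decreasing azimuth viewed from +z) and lies in
    (0, 2*pi]; endpoints at equal azimuth but different height therefore
    wind a full turn, as a loop constrained to one winding sense must.
    Closed form: length = sqrt(dz**2 + (r * dphi)**2).  ``a == b`` yields
    a zero-length path.
    """
    if winding not in ("clockwise", "counterclockwise"):
        raise ValueError(f"winding must be clockwise/counterclockwise: {winding!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, b):
        return SurfacePath(points=np.array([a, b]), length_nm=0.0, winding=winding)
    if math.hypot(*a[:2]) < 1e-12 or math.hypot(*b[:2]) < 1e-12:
        raise ValueError("endpoints must lie off the core axis")
    r = scaffold.params.radius_nm + scaffold.params.probe_nm
    phi_a = math.atan2(a[1], a[0])
    phi_b = math.atan2(b[1], b[0])
    if winding == "counterclockwise":
        dphi = (phi_b - phi_a) % (2 * math.pi)
        sign = 1.0
    else:
        dphi = (phi_a - phi_b) % (2 * math.pi)
        sign = -1.0
    if dphi == 0.0:
        dphi = 2 * math.pi
    dz = b[2] - a[2]
    length = math.hypot(dz, r * dphi)
    t = np.linspace(0.0, 1.0, n_segments + 1)
    phi = phi_a + sign * dphi * t
    pts = np.column_stack(
        (r * np.cos(phi), r * np.sin(phi), a[2] + dz * t)
    )
    return SurfacePath(points=pts, length_nm=length, winding=winding)


def propeller_path_table(
    n_tetrads: int = 3,
    helicities: Sequence[Helicity] = ("RH", "LH"),
    params: ScaffoldParams = ScaffoldParams(),
) -> pd.DataFrame:
    """Surface-path lengths of every propeller loop across all valid
    topologies and the requested helicities.

    A ``+p`` loop winds clockwise, a ``-p`` loop counterclockwise (the
    direction of strand progression).  Columns: topology, helicity,
    position, geometry_label, path_length_nm.
    """
    rows = []
    for helicity in helicities:
        scaffold = build_scaffold(n_tetrads, helicity, params)
        for topo in enumerate_topologies():
            trace = topo.trace
            labels = classify_propellers_rule(topo, helicity)
            for k, lt in enumerate(topo.loops):
                if not lt.is_propeller:
                    continue
                a, b = loop_attachment_pair(scaffold, trace, k)
                winding = "clockwise" if lt.sign > 0 else "counterclockwise"
                path = shortest_surface_path(scaffold, a, b, winding)
                rows.append(
                    {
                        "topology": str(topo),
                        "helicity": helicity,
                        "position": ("I", "II", "III")[k],
                        "geometry_label": labels[k],
                        "path_length_nm": path.length_nm,
                    }
                )
    return pd.DataFrame(rows)


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD between two ordered point sets after optimal rigid
    superposition (proper rotation + translation, no reflection).

    Standard Kabsch algorithm via SVD with determinant correction.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3): {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A @ R.T - B
    return float(np.sqrt((diff**2).sum() / n))


def write_scaffold_pdb(scaffold: Scaffold, path: str) -> None:
    """Write the scaffold anchors as pseudo-atoms in PDB format.

    One chain per tract (A-D), one residue per tetrad level, a single
    C1' pseudo-atom per anchor; coordinates in Angstrom per PDB
    convention (scaffold geometry is in nm).  Readable by any standard
    PDB parser.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = 4 * scaffold.n_tetrads
    atoms = struc.AtomArray(n_atoms)
    i = 0
    for c in range(4):
        for level in range(scaffold.n_tetrads):
            atoms.coord[i] = scaffold.anchors[c, level] * 10.0  # nm -> A
            atoms.chain_id[i] = "ABCD"[c]
            atoms.res_id[i] = level + 1
            atoms.res_name[i] = "DG"
            atoms.atom_name[i] = "C1'"
            atoms.element[i] = "C"
            atoms.hetero[i] = False
            i += 1
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(path)
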