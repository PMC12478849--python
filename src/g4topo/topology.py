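"""Loop types, looping topologies and the conformational grid.

A unimolecular G-quadruplex (G4) threads a single DNA strand through four
G-tracts arranged on the corners of a square prism of stacked G-tetrads.
Three loops connect consecutive tracts; each loop is one of five types:

* propeller (``+p`` / ``-p``) -- connects the bottom tetrad of one tract to
  the top tetrad of the adjacent tract, clockwise (``+``) or anticlockwise
  (``-``) when viewed from the top; strand direction is preserved,
* lateral (``+l`` / ``-l``) -- connects adjacent tracts within the same
  tetrad; strand direction reverses,
* diagonal (``d``) -- connects diagonally opposite tracts within the same
  tetrad; strand direction reverses; has no sign.

Walking the strand from the 5' end and requiring the four tracts to occupy
the four distinct corners (and the two diagonal loops, when present, to lie
on opposite tetrad faces) leaves 26 valid looping topologies out of the
5**3 = 125 conceivable loop triples.  The conformational grid crosses these
topologies with tetrad-polarity patterns, helicity and per-loop lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "LoopKind",
    "LoopType",
    "Topology",
    "TopologyTrace",
    "TopologyError",
    "Helicity",
    "parse_topology",
    "format_topology",
    "trace_topology",
    "is_valid_topology",
    "enumerate_topologies",
    "enumerate_polarity_patterns",
    "Conformation",
    "enumerate_conformations",
    "conformations_to_frame",
    "frame_to_conformations",
    "CONFORMATION_COLUMNS",
]


class TopologyError(ValueError):
    """Raised for malformed topology notation or invalid loop triples."""


class LoopKind(str, Enum):
    PROPELLER = "p"
    LATERAL = "l"
    DIAGONAL = "d"


class LoopType(Enum):
    """One of the five loop types, identified by its ASCII token."""

    LAT_MINUS = "-l"
    PROP_MINUS = "-p"
    LAT_PLUS = "+l"
    PROP_PLUS = "+p"
    DIAGONAL = "d"

    def __str__(self) -> str:  # canonical ASCII token
        return self.value

    @property
    def kind(self) -> LoopKind:
        return LoopKind(self.value[-1])

    @property
    def sign(self) -> int:
        """+1 for clockwise, -1 for anticlockwise, 0 for diagonal."""
        if self is LoopType.DIAGONAL:
            return 0
        return 1 if self.value[0] == "+" else -1

    @property
    def corner_step(self) -> int:
        """Corner increment of the strand walk (mod 4)."""
        return 2 if self is LoopType.DIAGONAL else self.sign

    @property
    def is_propeller(self) -> bool:
        return self.kind is LoopKind.PROPELLER

    @property
    def mirror(self) -> "LoopType":
        """Same kind with the sign reversed (diagonal maps to itself)."""
        if self is LoopType.DIAGONAL:
            return self
        return LoopType(("-" if self.value[0] == "+" else "+") + self.value[1])


#: Frozen canonical ordering of loop tokens used for enumeration output.
CANONICAL_LOOP_ORDER: tuple[LoopType, ...] = (
    LoopType.LAT_MINUS,
    LoopType.PROP_MINUS,
    LoopType.LAT_PLUS,
    LoopType.PROP_PLUS,
    LoopType.DIAGONAL,
)

_RANK = {lt: i for i, lt in enumerate(CANONICAL_LOOP_ORDER)}

# Unicode minus (U+2212), en/em dashes -> ASCII hyphen before parsing.
_DASH_TABLE = str.maketrans({"−": "-", "–": "-", "—": "-"})

Helicity = str  # "RH" | "LH"

_HELICITIES = ("RH", "LH")


def _check_helicity(helicity: str) -> str:
    if helicity not in _HELICITIES:
        raise ValueError(f"helicity must be 'RH' or 'LH', got {helicity!r}")
    return helicity


def _tokenize(text: str) -> list[LoopType]:
    text = text.strip().translate(_DASH_TABLE)
    tokens: list[LoopType] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "d":
            tokens.append(LoopType.DIAGONAL)
            i += 1
        elif ch in "+-":
            if i + 1 >= len(text) or text[i + 1] not in "pl":
                bad = text[i : i + 2] or ch
                raise TopologyError(
                    f"malformed loop token {bad!r} at position {i} in {text!r}"
                    " (expected 'p' or 'l' after the sign; 'd' takes no sign)"
                )
            tokens.append(LoopType(text[i : i + 2]))
            i += 2
        else:
            raise TopologyError(
                f"malformed loop token {ch!r} at position {i} in {text!r}"
            )
    return tokens


@dataclass(frozen=True)
class TopologyTrace:
    """Result of the strand-continuity walk over a loop triple.

    Attributes
    ----------
    corners
        Corner index (0-3 on the tetrad square, increasing clockwise viewed
        from the top) occupied by each of the four tracts in strand order.
        The 5' tract sits at corner 0 by convention.
    directions
        Per-tract strand direction, ``up`` or ``down``.  The first tract
        runs up; propeller loops preserve the direction, lateral and
        diagonal loops reverse it.
    loop_faces
        Tetrad face on which each loop lies: ``top``/``bottom`` for lateral
        and diagonal loops (the exit face of the preceding tract),
        ``spanning`` for propellers, which bridge both faces.
    """

    corners: tuple[int, int, int, int]
    directions: tuple[str, str, str, str]
    loop_faces: tuple[str, str, str]


def trace_topology(loops: Sequence[LoopType]) -> TopologyTrace:
    """Walk the strand 5'->3' through a loop triple.

    Works on any triple, valid or not; validity is judged afterwards from
    the trace (see :func:`is_valid_topology`).
    """
    if len(loops) != 3:
        raise TopologyError(f"expected 3 loops, got {len(loops)}")
    corner, direction = 0, 1  # corner 0, running up
    corners = [0]
    directions = [direction]
    faces: list[str] = []
    for lt in loops:
        if lt.is_propeller:
            faces.append("spanning")
        else:
            faces.append("top" if direction == 1 else "bottom")
            direction = -direction
        corner = (corner + lt.corner_step) % 4
        corners.append(corner)
        directions.append(direction)
    return TopologyTrace(
        corners=tuple(corners),
        directions=tuple("up" if d == 1 else "down" for d in directions),
        loop_faces=tuple(faces),
    )


def is_valid_topology(loops: Sequence[LoopType]) -> bool:
    """True iff the triple threads all four corners once and its diagonal
    loops (if two) lie on opposite tetrad faces."""
    trace = trace_topology(loops)
    if len(set(trace.corners)) != 4:
        return False
    diag_faces = [
        face
        for lt, face in zip(loops, trace.loop_faces)
        if lt is LoopType.DIAGONAL
    ]
    return len(diag_faces) == len(set(diag_faces))


@dataclass(frozen=True, order=False)
class Topology:
    """An ordered triple of loop types (positions I, II, III).

    Instances are validated on construction; use :func:`trace_topology`
    directly to inspect invalid triples.
    """

    loops: tuple[LoopType, LoopType, LoopType]

    def __post_init__(self) -> None:
        loops = tuple(self.loops)
        object.__setattr__(self, "loops", loops)
        if not is_valid_topology(loops):
            raise TopologyError(
                f"{format_topology(loops)!r} is not a valid looping topology"
            )

    def __str__(self) -> str:
        return format_topology(self.loops)

    def __repr__(self) -> str:
        return f"Topology({format_topology(self.loops)!r})"

    def __iter__(self) -> Iterator[LoopType]:
        return iter(self.loops)

    @property
    def trace(self) -> TopologyTrace:
        return trace_topology(self.loops)

    @property
    def mirror(self) -> "Topology":
        """Topology with every signed loop's sign reversed (always valid)."""
        return Topology(tuple(lt.mirror for lt in self.loops))

    def sort_key(self) -> tuple[int, int, int]:
        return tuple(_RANK[lt] for lt in self.loops)  # type: ignore[return-value]


def format_topology(loops: Sequence[LoopType]) -> str:
    """Canonical ASCII notation, e.g. ``-pd+l``."""
    return "".join(lt.value for lt in loops)


def parse_topology(text: str) -> Topology:
    """Parse topology notation such as ``-pd+l`` (Unicode minus accepted).

    Raises
    ------
    TopologyError
        On malformed tokens, a wrong token count, or a triple that fails
        the strand-continuity validity test.
    """
    tokens = _tokenize(text)
    if len(tokens) != 3:
        raise TopologyError(
            f"{text!r} contains {len(tokens)} loop tokens, expected 3"
        )
    return Topology(tuple(tokens))


def enumerate_topologies() -> list[Topology]:
    """All 26 valid looping topologies in frozen canonical order.

    Brute-forces the 125 loop triples through :func:`is_valid_topology`;
    output order is lexicographic over tokens (-l < -p < +l < +p < d).
    """
    return [
        Topology(triple)
        for triple in itertools.product(CANONICAL_LOOP_ORDER, repeat=3)
        if is_valid_topology(triple)
    ]


PolarityPattern = tuple[str, ...]  # per-tetrad "LP"/"RP", ordered bottom->top


def enumerate_polarity_patterns(n_tetrads: int) -> list[PolarityPattern]:
    """All 2**n assignments of tetrad polarity (LP/RP), bottom tetrad first."""
    if n_tetrads < 1:
        raise ValueError(f"n_tetrads must be >= 1, got {n_tetrads}")
    return list(itertools.product(("LP", "RP"), repeat=n_tetrads))


@dataclass(frozen=True)
class Conformation:
    """One cell of the conformational grid.

    ``topology`` x ``helicity`` x ``n_tetrads`` x ``polarity`` x
    ``loop_lengths`` identifies a unique target conformation of a sequence
    G(n)T(i) G(n)T(j) G(n)T(k) G(n) with all-thymine loops.
    """

    topology: Topology
    helicity: Helicity
    n_tetrads: int
    polarity: PolarityPattern
    loop_lengths: tuple[int, int, int]

    def __post_init__(self) -> None:
        _check_helicity(self.helicity)
        if len(self.polarity) != self.n_tetrads:
            raise ValueError(
                f"polarity pattern length {len(self.polarity)} != "
                f"n_tetrads {self.n_tetrads}"
            )
        if any(p not in ("LP", "RP") for p in self.polarity):
            raise ValueError(f"polarity values must be LP/RP: {self.polarity}")
        if len(self.loop_lengths) != 3 or any(l < 1 for l in self.loop_lengths):
            raise ValueError(f"loop lengths must be 3 positive ints: {self.loop_lengths}")

    @property
    def conformation_id(self) -> str:
        """Stable unique identifier, e.g. ``3T-RH|-pd+p|LP.RP.LP|1.3.1``."""
        return "|".join(
            (
                f"{self.n_tetrads}T-{self.helicity}",
                str(self.topology),
                ".".join(self.polarity),
                ".".join(str(l) for l in self.loop_lengths),
            )
        )

    @property
    def sequence(self) -> str:
        """The all-thymine-loop DNA sequence realizing this conformation."""
        g = "G" * self.n_tetrads
        i, j, k = self.loop_lengths
        return g + "T" * i + g + "T" * j + g + "T" * k + g


def enumerate_conformations(
    n_tetrads: int,
    loop_length_range: tuple[int, int] = (1, 4),
    helicity: Helicity = "RH",
    topologies: Iterable[Topology] | None = None,
) -> list[Conformation]:
    """Cartesian product of loop-length triples x topologies x polarity
    patterns at a fixed helicity.

    With the default 1-4 nt range this yields 64 sequences per tetrad
    class and 26 x 2**n_tetrads conformations per sequence: 13,312
    three-tetrad or 6,656 two-tetrad conformations.
    """
    _check_helicity(helicity)
    lo, hi = loop_length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid loop length range {loop_length_range}")
    topo_list = list(topologies) if topologies is not None else enumerate_topologies()
    polarities = enumerate_polarity_patterns(n_tetrads)
    lengths = range(lo, hi + 1)
    return [
        Conformation(
            topology=topo,
            helicity=helicity,
            n_tetrads=n_tetrads,
            polarity=pol,
            loop_lengths=(i, j, k),
        )
        for (i, j, k) in itertools.product(lengths, repeat=3)
        for topo in topo_list
        for pol in polarities
    ]


CONFORMATION_COLUMNS = [
    "conformation_id",
    "n_tetrads",
    "helicity",
    "topology",
    "polarity",
    "len_I",
    "len_II",
    "len_III",
]


def conformations_to_frame(conformations: Iterable[Conformation]) -> pd.DataFrame:
    """Tabulate conformations in the interchange TSV schema."""
    rows = [
        {
            "conformation_id": c.conformation_id,
            "n_tetrads": c.n_tetrads,
            "helicity": c.helicity,
            "topology": str(c.topology),
            "polarity": ".".join(c.polarity),
            "len_I": c.loop_lengths[0],
            "len_II": c.loop_lengths[1],
            "len_III": c.loop_lengths[2],
        }
        for c in conformations
    ]
    return pd.DataFrame(rows, columns=CONFORMATION_COLUMNS)


def frame_to_conformations(frame: pd.DataFrame) -> list[Conformation]:
    """Inverse of :func:`conformations_to_frame`."""
    return [
        Conformation(
            topology=parse_topology(row.topology),
            helicity=row.helicity,
            n_tetrads=int(row.n_tetrads),
            polarity=tuple(row.polarity.split(".")),
            loop_lengths=(int(row.len_I), int(row.len_II), int(row.len_III)),
        )
        for row in frame.itertuples(index=False)
    ]
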