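"""Loop-length feasibility rules for G-quadruplex topologies.

Survey-derived minimum loop lengths: diagonal loops need at least 3 nt,
lateral loops at least 2 nt (a single 1-nt +l structure is known, hence
the ``strict_lateral`` switch), short-distance propellers form with 1 nt,
and long-distance propellers need 5 nt or more.  Treating these minima as
hard constraints turns a loop-length triple into a feasible set of
topologies, and inverting the question yields sequence designs that
uniquely (or nearly uniquely) select a target topology -- e.g. lengths
(1, >=3, 1) leave only -pd+p and -p-p-p feasible under RH helicity.
Binary feasibility is a deliberate simplification of the graded
foldability penalties seen in simulation data.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

from .geometry import classify_propellers_rule
from .topology import Conformation, Helicity, LoopKind, Topology, enumerate_topologies

__all__ = [
    "RuleSet",
    "Violation",
    "FeasibilityResult",
    "is_feasible",
    "feasible_topologies",
    "DesignCandidate",
    "design_search",
]


@dataclass(frozen=True)
class RuleSet:
    """Minimum loop lengths (nt) per loop geometry.

    ``min_ld_propeller_nt_two_tetrad`` optionally relaxes the LD minimum
    for two-tetrad cores, whose shorter attachment paths tolerate shorter
    LD loops; by default the same rules apply to both tetrad counts.
    """

    min_lateral_nt: int = 2
    min_diagonal_nt: int = 3
    min_sd_propeller_nt: int = 1
    min_ld_propeller_nt: int = 5
    strict_lateral: bool = True
    min_ld_propeller_nt_two_tetrad: int | None = None

    def __post_init__(self) -> None:
        minima = (
            self.min_lateral_nt,
            self.min_diagonal_nt,
            self.min_sd_propeller_nt,
            self.min_ld_propeller_nt,
        )
        if any(m < 1 for m in minima if math.isfinite(m)):
            raise ValueError(f"all minima must be >= 1: {self}")
        if self.min_ld_propeller_nt < self.min_sd_propeller_nt:
            raise ValueError("min_ld_propeller_nt must be >= min_sd_propeller_nt")

    def minimum_for(self, kind: LoopKind, geometry: str, n_tetrads: int = 3) -> float:
        """Minimum length for a loop of ``kind`` with SD/LD ``geometry``."""
        if kind is LoopKind.DIAGONAL:
            return self.min_diagonal_nt
        if kind is LoopKind.LATERAL:
            return self.min_lateral_nt if self.strict_lateral else 1
        if geometry == "LD":
            if n_tetrads == 2 and self.min_ld_propeller_nt_two_tetrad is not None:
                return self.min_ld_propeller_nt_two_tetrad
            return self.min_ld_propeller_nt
        return self.min_sd_propeller_nt

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class Violation:
    position: str  # "I" | "II" | "III"
    loop: str  # loop token
    geometry: str  # "SD" | "LD" | "NA"
    length: int
    required_min: float

    def __str__(self) -> str:
        kind = self.loop if self.geometry == "NA" else f"{self.geometry} {self.loop}"
        return (
            f"position {self.position}: {kind} loop of {self.length} nt "
            f"< minimum {self.required_min:g} nt"
        )


@dataclass(frozen=True)
class FeasibilityResult:
    feasible: bool
    violations: tuple[Violation, ...]

    def __bool__(self) -> bool:
        return self.feasible


def is_feasible(
    conformation: Conformation, rules: RuleSet = RuleSet()
) -> FeasibilityResult:
    """Check every loop length against the minimum for its geometry.

    Propeller minima are selected by the SD/LD label at the
    conformation's helicity.
    """
    labels = classify_propellers_rule(conformation.topology, conformation.helicity)
    violations = []
    for k, (lt, length, label) in enumerate(
        zip(conformation.topology.loops, conformation.loop_lengths, labels)
    ):
        minimum = rules.minimum_for(lt.kind, label, conformation.n_tetrads)
        if length < minimum:
            violations.append(
                Violation(
                    position=("I", "II", "III")[k],
                    loop=str(lt),
                    geometry=label,
                    length=length,
                    required_min=minimum,
                )
            )
    return FeasibilityResult(feasible=not violations, violations=tuple(violations))


def feasible_topologies(
    loop_lengths: Sequence[int],
    helicity: Helicity = "RH",
    rules: RuleSet = RuleSet(),
    n_tetrads: int = 3,
    polarity: tuple[str, ...] | None = None,
) -> list[Topology]:
    """Topologies (canonical order) a loop-length triple can adopt.

    Polarity never enters the length rules; a fixed pattern is used
    internally to build the probe conformations.
    """
    lengths = tuple(int(l) for l in loop_lengths)
    if len(lengths) != 3 or any(l < 1 for l in lengths):
        raise ValueError(f"loop_lengths must be 3 positive ints: {loop_lengths}")
    pol = polarity if polarity is not None else ("LP",) * n_tetrads
    out = []
    for topo in enumerate_topologies():
        conf = Conformation(
            topology=topo,
            helicity=helicity,
            n_tetrads=n_tetrads,
            polarity=pol,
            loop_lengths=lengths,
        )
        if is_feasible(conf, rules):
            out.append(topo)
    return out


@dataclass(frozen=True)
class DesignCandidate:
    loop_lengths: tuple[int, int, int]
    competitors: tuple[str, ...]  # competing topologies, canonical notation

    @property
    def n_competitors(self) -> int:
        return len(self.competitors)

    @property
    def total_length(self) -> int:
        return sum(self.loop_lengths)


def design_search(
    target: Topology,
    helicity: Helicity = "RH",
    rules: RuleSet = RuleSet(),
    max_len: int = 4,
    n_tetrads: int = 3,
) -> list[DesignCandidate]:
    """Loop-length triples (each <= ``max_len``) at which ``target`` is
    feasible, ranked by how few competing topologies remain feasible.

    Ties break by ascending total loop length, then lexicographically.
    Returns an empty list when the target is infeasible at every triple
    (e.g. +p+p+p under RH with max_len < 5).
    """
    candidates = []
    for lengths in itertools.product(range(1, max_len + 1), repeat=3):
        feas = feasible_topologies(lengths, helicity, rules, n_tetrads)
        names = [str(t) for t in feas]
        if str(target) not in names:
            continue
        competitors = tuple(n for n in names if n != str(target))
        candidates.append(DesignCandidate(loop_lengths=lengths, competitors=competitors))
    candidates.sort(
        key=lambda c: (c.n_competitors, c.total_length, c.loop_lengths)
    )
    return candidates
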