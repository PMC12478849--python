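"""Sequence design for the unreported -pd+p topology.

-pd+p is the only right-handed topology without long-distance propellers
that has never been solved at high resolution.  Searching loop-length
triples for configurations where it is feasible, ranked by how few
competing topologies survive the length rules, recovers the design
recommendation: 1-nt loops at positions I and III with a >=3-nt loop at
position II, leaving -p-p-p as the only competitor.
"""

from g4topo.feasibility import design_search, feasible_topologies
from g4topo.topology import parse_topology

target = parse_topology("-pd+p")
candidates = design_search(target, "RH", max_len=4)
print(f"{len(candidates)} loop-length triples admit {target}; best designs:")
for cand in candidates[:5]:
    print(
        f"  loops {cand.loop_lengths}  total {cand.total_length} nt  "
        f"competitors: {', '.join(cand.competitors) or 'none'}"
    )

lengths = candidates[0].loop_lengths
print(f"\nfeasible set at {lengths}: "
      f"{[str(t) for t in feasible_topologies(lengths, 'RH')]}")
# With loops (1, 3, 1) only -pd+p and -p-p-p pass the length rules; a
# sequence G3-T-G3-TTT-G3-T-G3 is the minimal candidate, competing only
# with the ubiquitous all-propeller fold.
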