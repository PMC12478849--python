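"""Enumerate the valid looping topologies of a unimolecular G-quadruplex.

Walks the strand through every one of the 125 conceivable loop triples
and keeps those that place the four G-tracts on four distinct corners
(with diagonal loops on opposite faces when there are two).
"""

import g4topo as g

topologies = g.enumerate_topologies()
print(f"{len(topologies)} valid looping topologies out of 125 loop triples:")
for topo in topologies:
    trace = topo.trace
    print(f"  {str(topo):8s} corners {trace.corners}  directions {trace.directions}")

# 26 is the number of standard unimolecular G4 topologies: every triple of
# propeller/lateral/diagonal loops that keeps the strand threading all four
# corners of the tetrad square exactly once.
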