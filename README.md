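# g4topo

Geometric analysis of the topological landscape of unimolecular
G-quadruplexes (G4s).

A G4 threads one DNA strand through four G-tracts stacked into 2–3
guanine tetrads; the three connecting loops are each propeller
(`+p`/`-p`), lateral (`+l`/`-l`) or diagonal (`d`). `g4topo` answers,
from geometry alone, which of the conceivable folds are real and why:

* **Topology enumeration** — walking the strand over the tetrad square
  and requiring the four tracts to occupy distinct corners leaves **26
  valid looping topologies** out of 5³ = 125 loop triples.
* **Propeller loop geometry** — each propeller loop is *short-distance*
  (SD) or *long-distance* (LD) depending on its winding, its position and
  the helicity. Closed-form rule (right-handed helicity): `+p` is LD iff
  0 or 2 non-propeller loops precede it; `-p` is LD iff exactly 1 does;
  left-handed helicity swaps every label. 12 of the 26 topologies carry
  LD propellers; an independent 2D-unwrap classifier and 3D surface-path
  lengths on an idealized core scaffold confirm the dichotomy.
* **Feasibility rules** — survey minima (lateral ≥ 2 nt, diagonal ≥ 3 nt,
  LD propeller ≥ 5 nt) turn loop lengths into feasible topology sets and
  support sequence design (e.g. loops (1, 3, 1) admit only `-pd+p` and
  `-p-p-p`).
* **Foldability statistics** — RMSD-threshold fold classification
  (per-class 99th-percentile thresholds, strict `rmsd < t`), foldability
  maps over topology × total loop length, per-position feature tables, a
  gradient-boosted foldability classifier with stratified CV precision,
  and **exact Shapley attribution** by full coalition enumeration with
  retrain-per-coalition value functions.
* **Synthetic data** — a generator whose fold log-odds encode the LD
  penalty (with length relief vanishing at 5 nt), loop-length benefits
  and hard violations, emitting threshold-separable RMSD values, so the
  entire pipeline is testable without any external dataset.

## Worked example

```sh
python examples/simulate_and_analyze.py
```

generates the complete three-tetrad right-handed grid (13,312
conformations), labels it and analyzes it:

```
13312 conformations, foldable fraction 0.377

most / least foldable topologies:
-p-p-p    0.961
+l+p+p    0.732
...
+pd-p     0.076
+p+p+p    0.074

10-fold CV precision 0.922 (prevalence 0.377)

top favorable / unfavorable loop-type features (signed Shapley):
 type_I    -p            0.1828
 ...
 type_I    +p           -0.1599
```

The all-SD-propeller fold `-p-p-p` is almost always foldable while the
all-LD fold `+p+p+p` almost never is; the strongest favorable feature is
`-p` at position I (always SD under RH) and the strongest unfavorable one
is `+p` at position I (always LD) — the geometric signature of
long-distance propeller loops. Other entry points: `examples/
enumerate_topologies.py`, `propeller_census.py`, `surface_paths.py`,
`design_pdp_quadruplex.py`, and the `g4topo` CLI
(`g4topo enumerate|classify|feasible|simulate|label|map|attribute|run`).

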