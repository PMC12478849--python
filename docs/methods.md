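# Methods

## The topology model

A unimolecular G-quadruplex is modelled as four G-tracts on the corners
of a square prism of 2 or 3 stacked G-tetrads, connected 5'→3' by three
loops drawn from five types: propeller `+p`/`-p` (bridges bottom and top
tetrads of adjacent tracts, preserving strand direction; `+` = clockwise
viewed from the top), lateral `+l`/`-l` (same tetrad, adjacent tracts,
reversing direction) and diagonal `d` (same tetrad, opposite tracts,
reversing direction, unsigned).

**Validity walk.** Corners are labelled 0–3 increasing clockwise viewed
from the top, with the 5' tract at corner 0 running up — a pure
convention; all results are rotation-invariant. Each loop steps the
corner index by +1 (`+p`, `+l`), −1 (`-p`, `-l`) or +2 (`d`), modulo 4.
Lateral and diagonal loops lie on the exit face of the current tract
(top if running up, bottom if down) and flip the direction; propellers
span both faces and keep it. A triple is a valid topology iff the four
visited corners are pairwise distinct and no two diagonal loops share a
face. This yields exactly 26 survivors of the 125 triples, partitioned
by step pattern as 8 + 8 + 4 + 4 + 1 + 1; the set is closed under
sign-reversal (mirror) and contains `d+pd`/`d-pd` as the only
double-diagonal forms. The criterion is our formalization of "strand and
tract continuity"; it reproduces the known count and all named members,
but other equivalent formulations exist.

**Canonical order and notation.** Topology notation concatenates loop
tokens (`-pd+l`); Unicode minus and dashes are normalized to ASCII `-`
on parsing, and enumeration output is frozen in lexicographic token
order `-l < -p < +l < +p < d`.

**Conformational grid.** Conformations cross the 26 topologies with
helicity (RH/LH), tetrad count (2 or 3), all 2^n tetrad-polarity
patterns (LP/RP per tetrad, ordered bottom→top; the ordering is
arbitrary since polarity never enters any geometric rule here) and
per-loop lengths 1–4 nt by default: 13,312 three-tetrad and 6,656
two-tetrad conformations (19,968 total) per helicity.

## Short- vs long-distance propellers

Stacking twist displaces the top tetrad azimuthally relative to the
bottom one, so a propeller loop's two attachment points are either
azimuthally close (SD) or far (LD). Writing s = loop sign (±1), d =
direction of the tract the loop exits (+1 up, −1 down) and σ = helicity
(+1 RH, −1 LH), the azimuthal span the loop must traverse in its own
winding direction is 90° + w·Δ with w = s·d·σ and Δ the total twist
across the core; w = +1 is the long-distance case. Since d flips once
per preceding non-propeller loop, this is equivalent to the counting
rule (RH): `+p` is LD iff 0 or 2 non-propeller loops precede it, `-p`
iff exactly 1; LH swaps all labels. The rule classifier is normative.

**2D unwrap.** The geometric cross-check unrolls the core cylinder
along the strand's initial winding direction (clockwise for a `-` first
loop, counterclockwise for `+`; for the two topologies that start with
`d`, the first signed loop decides). Tracts appear left-to-right in
strand order as columns of height 1 whose tops are displaced by the
in-plane image of the twist, τ = 0.35 tract-spacing units by default
(an arbitrary layout constant; only the SD/LD separation matters). The
in-plane tilt sign is the product of helicity and unwrap direction —
the faithful unrolled geometry — so LH projections mirror RH ones.
Each propeller's attachment pair is separated horizontally by
spacing·(1 + w·τ) travelled in the loop's own direction (a periodic
image when it opposes the unwrap). Propellers are labelled LD when the
attachment distance exceeds a threshold; any threshold strictly inside
the admissible band (hypot(1−τ, 1), hypot(1+τ, 1)) ≈ (1.193, 1.680)
reproduces the rule on all 52 (topology, helicity) cases, and the
default is the band midpoint, computed at import from the 52 cases.

## 3D scaffold and surface paths

The scaffold is an idealized stand-in for folded structures: anchors at
radius 1.0 nm, rise 0.34 nm and twist 30°/tetrad (canonical
nucleic-acid stacking geometry, configurable), signed by helicity. A
loop path is a single-winding geodesic on a guard cylinder (anchor
radius + 0.2 nm probe): length = sqrt(Δz² + (r·Δφ)²) with Δφ ∈ (0, 2π]
the azimuthal span in the loop's mandated direction (`+` clockwise, `-`
counterclockwise; lateral/diagonal paths, used only informally, take
the shorter winding). Whether the "shortest admissible loop route" of a
real structure is best modelled as a surface geodesic, an atom-graph
path or a clipped straight line is an open modelling choice; the
geodesic is the simplest deterministic option that preserves the
SD/LD dichotomy. Consequences on the default three-tetrad scaffold:
SD paths are all 0.93 nm and LD paths 3.21 nm (disjoint populations);
two-tetrad LD paths (2.54 nm) are shorter than three-tetrad ones,
matching the observation that two-tetrad cores tolerate LD loops more
readily. Absolute lengths are idealized-geometry quantities, not
ensemble means, and are not comparable to trajectory-derived values.

Superposition RMSD uses the Kabsch algorithm (SVD with determinant
correction; proper rotations only), cross-checked in the tests against
MDAnalysis' independent implementation. Scaffolds export as PDB
pseudo-atoms (biotite; chains A–D, one residue per tetrad level,
Angstrom).

## Feasibility rules

Minimum loop lengths: lateral 2 nt (switchable to 1 via
`strict_lateral=False`, motivated by the single known 1-nt `+l`
structure), diagonal 3 nt, SD propeller 1 nt, LD propeller 5 nt.
Propeller minima are selected by the SD/LD label at the conformation's
helicity. Treating the minima as hard constraints is a deliberate
binarization of graded penalties (3–4-nt LD loops are rare, not
impossible); the LD minimum is therefore exposed in `RuleSet`, along
with an optional two-tetrad LD override reflecting the laxer
constraints of shallower cores (off by default). Feasible sets are
monotone under loop lengthening by construction. The design search
ranks length triples admitting a target topology by competing-set size,
then total length, then lexicographically.

## Foldability pipeline

* **Thresholding:** per-class thresholds keyed `"<n>T-<helicity>"`;
  percentile method is linear interpolation between order statistics
  (numpy default), frozen; classification is strictly `rmsd <
  threshold`. The default constants 0.104/0.079/0.083 nm (99th
  percentile) describe reference folded-core fluctuation distributions
  and pair with the synthetic emissions below; for ingested data they
  should be recomputed from that data's folded traces.
* **Aggregation:** foldability maps average the foldable fraction per
  (topology, total loop length), rows ordered by decreasing topology
  mean; empty cells are missing, not zero. Feature tables group by loop
  type or length per position; two-loop tables cover ordered position
  pairs and list the member topologies (a single-member combination
  equals that topology's foldability).
* **Classifier:** features are loop type at I/II/III (categorical),
  loop length at I/II/III (integer) and the polarity pattern as one
  categorical (one-hot encoded) — 7 features. Default model is an
  XGBoost classifier (150 trees, depth 4, single-thread hist);
  precision over stratified 10-fold CV is the reported metric, with
  foldable as the positive class and seed default 20250911.
* **Shapley attribution:** exact enumeration over all 2^m coalitions
  (m ≤ 12 enforced; larger sets are directed to sampling). The value of
  coalition S for a record is the predicted foldability of a model
  retrained on feature subset S; the empty coalition predicts the base
  rate. Attributions are signed means (per-record efficiency:
  contributions sum to full prediction − base rate, exact to machine
  precision). Per-level summaries average a feature's per-record
  attributions over records sharing a level, the per-level reading of
  a Shapley summary plot.

## Synthetic data generator

Fold log-odds are additive: base 2.5; +0.3 per loop nucleotide above 1
(capped at 4 nt); −7.0 per LD propeller at 1 nt, relaxed linearly to 0
at 5 nt (the LD length floor); −9.0 per hard violation (diagonal < 3
nt, lateral < 2 nt); label noise 0.02 flips the latent Bernoulli
outcome. RMSD emissions are truncated normals (lower bound 0): folded
mean 0.06 nm, sd 0.015; misfolded mean 0.20 nm, sd 0.05 — chosen so the
default thresholds fall between the classes. Per-conformation RNG
streams derive from the global seed plus a CRC32 of the conformation
id, so any grid subset reproduces the full run's draws.

These defaults were chosen once to place the generated landscape in the
qualitative regime of simulation-derived foldability data — the all-SD
fold near-certain (≈0.96 here), the all-LD fold near-hopeless (≈0.05),
1-nt LD loops infeasible, foldability monotone in LD count and
recovering with loop length — and are documented as synthetic: the
generator emulates the *statistical shape* of such data (additive
penalties, threshold-separable emissions), not trajectories, force
fields, polarity effects (absent by construction) or nucleobase content
(loops are implicitly all-T). Passing tests therefore validate the
pipeline's correctness on data with this structure, not claims about
real G-quadruplexes.

Two generator-emergent caveats. (1) With the default emission overlap,
thresholding recovers the *emitted* outcome almost perfectly but
differs from the *latent* label by the noise rate plus an
emission-overlap term (≈0.016 at defaults); the label-recovery test
therefore uses a well-separated emission configuration (folded
0.06/0.008, misfolded 0.22/0.03) where the overlap term is negligible
by construction, so the measured error isolates the configured noise.
(2) The strong attribution signature — `-p` at position I most
favorable, `+p` at position I most unfavorable, reversed under LH — is
robust; the sign of the much weaker position-II propeller contrast is a
knife-edge quantity (a ~2-point foldability difference in the source
landscape) and is not reproduced reliably by an additive log-odds
generator, so tests assert the position-I pattern and the helicity
reversal only.

## Pipeline and determinism

`run_pipeline` chains enumerate → classify → simulate (or ingest) →
label → aggregate → attribute, exchanging TSV ('.'-decimal, header row)
and JSON, and writes a manifest with package version, config hash,
per-stage record counts and a SHA-256 checksum per emitted file; equal
configs produce byte-identical bundles. The attribution stage
subsamples to 4,000 records by default and uses depth-6 decision trees
as the retrained coalition model to keep 2^7 fits fast; both are
configurable. The ingest path accepts any per-conformation table with
the grid schema plus `rmsd_nm`, skipping simulation (noted in the
manifest).

Test-suite problem sizes: the statistical tests run on the full 13,312
three-tetrad grid, 10^5 draws for the percentile-vs-analytic-quantile
check and 4,000 records for binomial noise recovery — sizes at which
the checked asymptotics are comfortably in force while the whole suite
stays quick.

## Known limitations

Multimolecular G4s, bulged tracts, snapback/non-standard topologies and
G-register exchange are out of scope; the validity criterion is one
formalization among equivalent ones; surface paths are idealized (no
all-atom model building or clash detection); feasibility is binary;
thermodynamic ranking among feasible topologies is not attempted.
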