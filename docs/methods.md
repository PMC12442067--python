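# Methods

## Structure representation

A PBH is a set of fused hexagons. The authoritative object is the
**direction-annotated dualist graph**: one node per ring, one edge per fused
pair, each edge labelled with one of six lattice directions (multiples of
60°). Axial coordinates are derived from the directions by breadth-first
propagation, and an integer `layer` index separates rings that wind onto an
already-occupied cell, so helicenes are represented without ambiguity.
Coronoids (hexagon rings enclosing an empty cell) are rejected via the Euler
characteristic of the hexagon complex (atoms − bonds + rings must equal 1).

The carbon graph is built by union–find over ring-local vertices: fusing two
rings across a direction-*d* edge identifies the two shared atoms. Validity
checks: every atom has degree 2 (CH) or 3 (fusion), no atom in more than
three rings, and atom/bond counts consistent with the hexagon union. The
perimeter is the cycle of bonds that belong to exactly one ring; its **H/F
code** (H = CH vertex, F = fusion vertex) is canonicalized as the
lexicographically smallest rotation over both orientations, making it
independent of how the molecule was drawn.

**Constitutional-isomer identity** is a canonical code obtained by
breadth-first labelling of the dualist from every root under all 12 lattice
point symmetries (6 rotations × reflection), taking the lexicographic
minimum. Mirror images (and hence helical senses) are identified; layers
never enter the code. On every structure tested, two molecules receive the
same code exactly when their RDKit canonical SMILES coincide.

The `.hexlist` text format stores one `q r layer` triple per ring and infers
fusion from same-layer lattice adjacency. That inference is incomplete for
helicenes — [6]helicene's terminal rings are lattice-adjacent but *not*
fused — so the writer appends explicit `edge i j d` lines whenever
coordinate inference would not round-trip; parsing and writing are then
exact inverses in both directions.

## Annelation patterns and n_LL

A pyrene core is a 4-ring subset whose induced dualist is the pyrene rhombus
(two mutually fused *b* rings, each fused to both *a* rings) with the two
peri atoms present. Core rings are labelled by their degree in the core
subgraph (*a* = 2, *b* = 3); non-core rings fused to a core ring are
*attached*, the rest *remote*. The pattern is the multiset of core-ring
letters carrying at least one attached ring, written a-before-b. In a purely
cata-condensed space a core ring can never carry two attached rings — the
two exterior edges of an *a* ring share their middle CH atom — so the
letter-per-ring rule needs no tie-break in practice.

`n_LL` is the maximum number of rings on a dualist path whose consecutive
steps keep one lattice direction. The stretch may run through the core
(pyrene itself has n_LL = 2): the descriptor is a property of the whole
molecule, and restricting it to the non-core component would make the
five-ring members of the space indistinguishable from benzene. A toggle is
unnecessary — users needing the tail-only variant can run the function on
the tail subgraph.

## Clar analysis

A **Kekulé structure** is a perfect matching of the carbon graph, enumerated
by backtracking. A **Clar structure** places the maximum number of sextets on
pairwise vertex-disjoint rings such that the residual atoms still admit a
perfect matching (checked with Hopcroft–Karp; benzenoid graphs are
bipartite). All maximum placements are enumerated exhaustively — the fixed
count is the intersection of all placements, and migrating = total − fixed.

Two conventions are exposed:

* **Plain** (`clar_counts`): any ring may host a sextet. This is the
  standard Clar-cover definition.
* **Core-sextet convention** (`core_clar_counts`, used for the pattern
  table): sextets are kept off the two peri-fused core *b* rings. The
  parent pyrene's unique Clar structure places its two sextets on the *a*
  rings (the K-regions are localized double bonds); annelation makes those
  sextets migrate outward. Treating the *b* rings as double-bond scaffolding
  matches that resonance picture, and it is the convention under which the
  fixed/migrating split is *identical for every single-annelation isomer of
  a pattern* — the property that makes a pattern-level table well defined at
  all. Under the plain convention, benzo[a]pyrene has a third maximum
  placement (sextets on a core *b* ring and the attached ring) and the
  isomers of several patterns disagree.

Pattern-level counts (`pattern_delta_clar`) are computed over *all*
single-annelation isomers of the pattern and asserted equal before being
returned. The resulting ΔClar sequence over the ordering
aa, aab, a, aabb, ab, abb, b, bb is −2, −1, 0, 0, 1, 2, 3, 4. For **abb**
the counts are (total 4, fixed 3, migrating 1): total = fixed + migrating
is enforced as a hard invariant.

## Strain motifs and n_strain

Motifs are maximal runs of consecutive F (fusion) vertices on the perimeter,
flanked by H vertices: length 1 = fissure, 2 = bay, 3 = cove, 4 = fjord;
runs of five or more occur only in strongly wound helicenes and are tallied
separately as *helical* runs. Bays are attributed by the attached ring their
fusion vertices touch: attached-to-*a* → a-bay, attached-to-*b* → b-bay; a
bay entirely inside a remote tail is a generic phenanthrene-like H–H clash
and gets the a-bay weight 1. A bay touching both kinds of attached ring
would be reported as an error, never guessed; no such case exists in the
sample set.

Weights are derived from frozen-core reference strain energies of
single-motif molecules: each reference energy is divided by the a-bay
reference (2.6 kcal/mol) and by its motif count, then rounded to one decimal
(full precision behind a flag). The packaged defaults are the published
1 : 0.7 : 4.3 for a-bay : b-bay : cove. The cove reference energy is not
among the packaged constants; tests that need one use the value implied by
the weights (4.3 × 2 × 2.6 kcal/mol) and label it synthetic. Fissures are
unstrained; fjords and helical runs fall outside the three-term weighting
model and are excluded from the score (a warning is logged when present).

## The chemical space

`enumerate_space` grows structures breadth-first from pyrene: each child
fuses one benzene onto a *free edge* (both edge atoms in exactly one ring),
which keeps attachments cata-condensed by construction; duplicates are
removed at every size via the canonical code. Growth is unrestricted, and a
steric-feasibility filter is applied to the collected output:

* plain planar polyhexes are feasible;
* one unfused lattice adjacency — the [6]helicene motif — is feasible: the
  winding path twists out of plane and the clashing rings stack;
* a ring wound onto an occupied cell ([7]helicene and beyond) has climbed to
  the next layer and is feasible regardless of the adjacencies its planar
  drawing shows;
* two or more unfused adjacencies *without* any overlap pin a ring between
  neighbours it cannot twist away from; such molecules are not realizable
  and are excluded.

With this definition the 5–10-ring space contains **4,766** constitutional
isomers (per size: 2, 10, 40, 185, 818, 3711), of which 4,412 are planar
polyhexes. Disabling helicenic winding (`allow_helicenic=False`) returns the
planar subset. Every enumerated structure has exactly one pyrene core and
exactly two atoms in three rings, asserted in the tests.

The 13-molecule strain sample set is the `≤1 attached ring per core
position` sub-enumeration (each *a* ring offers two mirror-related free
edges, each *b* ring one). Members are named `<pattern>_sN` with N assigned
within a pattern by decreasing n_strain, ties broken by canonical code —
this pins the two-cove aab isomer to `aab_s1` and is stable across runs.

## Trends and the E_rel model

Relative energy is computed per ring-count cohort: E_rel = E_tot − min over
the cohort, with hartree inputs converted at 627.5095 kcal/mol. Pattern
summaries carry mean and standard deviation per property, the pattern-level
ΔClar, and the pattern's average n_strain — by default the mean over its
single-annelation sample isomers (1.0, 1.4, 2.0, 2.8, 3.7, 6.0, 6.4, 10.0
for a, b, aa, bb, ab, aab, abb, aabb), with a full-dataset mean as the
alternative mode. The E_rel model is plain ordinary least squares on the
eight pattern-level points; with the published coefficients
(α, β, γ) = (0.8, −0.3, 13.4) and the sample-set n_strain averages, the
predicted ordering is b < a < bb < aa < ab < abb < aab < aabb. No
significance machinery is attached: eight points support coefficient
estimates and R², nothing more.

## Synthetic data

`simulate_properties` generates per-molecule property tables as linear
functions of (pattern ΔClar, n_LL, n_strain) plus seeded Gaussian noise, and
a total-energy column (kcal/mol) set to the simulated E_rel plane, so that
cohort-relative energies reproduce the plane up to each cohort's minimum
shift while pattern means of the simulated E_rel column sit on it exactly. This reproduces the *statistical structure* the analysis assumes —
monotone pattern trends, additive descriptor effects, exact loop closure at
zero noise — but none of the physics it abstracts: real DFT properties are
not exactly linear in the descriptors, their noise is not homoscedastic
Gaussian, and size-dependence enters only through n_LL. Passing tests
therefore validate the analysis machinery, not the chemistry of any
particular dataset. Reproducing the published dataset-level fit
(R² = 0.8789) requires the external quantum-chemistry property tables,
which are deliberately not bundled; the dataset-level test instead runs the
identical pipeline on a simulated table over the enumerated space.

## Numerical choices and problem sizes

* Weight rounding: one decimal before scoring (matching the printed ratio);
  unrounded mode behind a flag.
* Canonicalization tie-breaks: lexicographic minima everywhere (perimeter
  rotation, BFS codes, sample-set naming).
* Clar search: subset search in decreasing cardinality with early
  termination; matchability via Hopcroft–Karp per component. Exhaustive, not
  merely optimizing — all maximum placements are produced.
* Test problem sizes: the oracle cross-checks (permanent-based Kekulé
  counts, powerset Clar search) run on ≤6-ring structures; invariant sweeps
  run on the full 5–7-ring slice plus a seeded 120-molecule sample of the
  full space; the complete 4,766-isomer enumeration runs once per session
  (~30 s).

## Known limitations

* No 3D geometry: dihedral angles, conformers and the frozen-core
  constrained optimization itself are out of scope; strain energies enter
  only as reference data.
* The steric-feasibility rule is combinatorial. It reproduces the intended
  space exactly, but molecules near its boundary (multiply-wound systems
  just above 10 rings) would need a geometric check.
* SMILES import handles fused all-carbon aromatic hexagon systems only — no
  substituents, heteroatoms or non-hexagonal rings.
* Patterns are defined for a single pyrene core; perylene- or
  coronene-cored systems are not classified.
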