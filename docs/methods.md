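# Methods

## The system

The δ protein of Orsay-like nematode viruses assembles into a pentameric
fiber that is incorporated into the T=3 virion as a CP-δ read-through
fusion. The fiber shaft is a stack of *β-bracelets*: rings in which each of
the five chains contributes one five-residue β-strand, closed by
three-residue loops, giving an exact period of 8 residues per chain per
ring. This package quantifies that architecture at four levels — sequence
(repeat detection and domain segmentation), length (an additive component
model), 3-D geometry (C5 axis, rise, tilt, radii) and assembly biochemistry
(oligomer order, stoichiometry, particle statistics) — and ships a
synthetic-data module that generates ground-truth-labelled inputs for all
of them.

## Consensus scanning (`motif_scan`)

A repeat window has nine consensus positions: strand P1–P5, loop P6–P8, and
the trailing anchor P9, which is simultaneously the next repeat's P1.
Constrained positions and their residue classes:

| position | strict | relaxed |
|---|---|---|
| P1 | {V, L} | hydrophobic φ = {A,V,L,I,M,F,W,Y,C} |
| P4 | {V} | φ |
| P6, P8 (loop flanks) | charged {D,E,K,R,H} | charged {D,E,K,R,H} |
| P7 (loop middle) | {E, D, N} | {D,E,K,R,H} ∪ {N,Q,S,T} |
| P9 | {V, L} | φ |

P2, P3 and P5 are wildcards: the observed preference for small/polar
residues there is a tendency, not a constraint, and scoring it would reject
genuine repeats. The strict classes are deliberately subsets of the relaxed
ones, so every strict match is a relaxed match.

A match score is the fraction of constrained positions satisfied
(`match_repeat_window`); the scanner (`scan_repeats`) accepts only perfect
matches and chains them into runs on an exact period-8 lattice. Runs
shorter than `min_run` (default 2 for de-novo scans; 1 when annotating a
known region) are discarded as isolated chance matches. When runs on
different lattice phases overlap, the longest run wins, ties to the
leftmost.

**Trailing anchor.** Interior repeats of a run automatically satisfy P9
through the next repeat's P1. The *final* repeat of a run is accepted
without its trailing anchor: the run has ended, so there is no following
strand whose P1 the position would be. (Requiring it would also reject a
bracelet region followed immediately by a non-repeat domain, which is
exactly the situation at the end of the first bracelet region.) A terminal
repeat whose loop is truncated by the sequence end is kept with
`loop_span = None`; only positions that exist in the sequence are checked.

**Strict ⊆ relaxed.** Class containment guarantees the strict *match set*
is a subset of the relaxed match set for every sequence
(`matching_starts`). After run assembly and overlap resolution the emitted
repeat lists can differ in pathological cases — a relaxed scan may see a
longer competing lattice that displaces the strict-phase run — so the
subset property is guaranteed (and property-tested) at the match level, and
holds for emitted repeats on any sequence without lattice conflicts.

**Domain segmentation.** `segment_domains` takes the strict and relaxed
repeat lists: bracelet region 1 is the strict-run span; bracelet region 2
spans relaxed runs downstream of it; the coiled coil, internal globular and
C-terminal globular domains are the flanking/intervening gaps (1-based
inclusive). With no repeats, an empty annotation with a warning flag is
returned rather than an error.

**Heptad assignment.** `assign_heptad` enumerates all seven register
phases, with and without one single-residue insertion ("stutter") at each
interior position, and keeps the configuration maximising summed
hydrophobicity (Kyte–Doolittle by default, configurable) at the `a`/`d`
positions. The stutter residue sits outside the heptad lattice and is
excluded from the score. An insertion is reported only when it beats the
best insertion-free register by `insertion_margin` (default 2.0 scale
units, roughly one clear hydrophobic). A hydrophobic-count margin was
considered and rejected: on helices whose non-`a/d` positions are weakly
hydrophobic (e.g. alanine-rich), misregistration does not change the count
at all, so a count margin cannot detect a stutter there. Note the stutter
is only localisable up to the window between its flanking `a`/`d`
hydrophobics — insertions at score-equivalent positions inside that window
are indistinguishable from `a/d` information alone; ties resolve to the
smallest phase, then the smallest insertion index.

## Additive length model (`fiber_model`)

`predict_length` = `l_crystal_region + n_extra_segments × h_segment +
d_internal + d_head`, all in Å. Defaults: `h_segment = 15 Å`, which is both
the stated per-segment height and the crystal-region rise (75 Å over five
repeats); it is overridable per virus. For the Orsay components
(145, 11, 15, 30, 50) the model sums to 390 Å. `infer_segment_count`
inverts the model and always reports the real-valued count alongside its
rounding — the segment number is an estimate, never silently an integer. A
measured length below the fixed components yields a negative count with a
warning (EM length distributions legitimately extend below the model
floor). `residues_per_height` charges whole axial units (a partial unit
costs a full unit's residues); the registered fold classes encode 8
(pentameric β-bracelet), 17 (trimeric β-spiral) and 31 (triple β-helix)
residues per chain per 15 Å unit.

Whether the 30 Å internal globule should be included for Santeuil/Le Blanc
(whose fibers show no internal globule in EM despite carrying the
corresponding sequence) is left to the caller: the component is an explicit
field, not a hard-coded constant.

## Pentamer geometry (`geometry`)

**Axis.** The C5 axis is extracted from the five rigid rotations that
superpose each chain onto its cyclic successor (Kabsch over shared Cα
positions), rather than from an inertia tensor: for a short fiber the
inertia axes are poorly conditioned, while pairwise rotations directly
certify the symmetry — each pair's rotation angle must fall within
`angle_tol` (default 5°) of 72°, otherwise a `SymmetryError` reports the
fitted angle. Axis directions are sign-aligned and averaged; each pair's
axis point is taken as the screw-axis solution of `(I−R)p = t⊥` (least
squares) slid to the foot of the global centroid. `mean_rotation_error` is
the mean pair RMSD.

**Rise** projects per-repeat centroids (all chains pooled) onto the axis
and averages consecutive spacings; non-monotone repeat order is an error,
and a single spacing reports its sd as absent. **Strand tilt** fits a
principal line (SVD) through each strand's Cα on every chain and takes the
acute angle to the axis; spans with fewer than three distinct points are
skipped and counted. **Radial profiles** bin selected atoms (`ca`,
`mainchain`, `all`) axially and report mean/min/max radius per bin;
diameters are 2×radius, and the selector is how "measured from main chain"
versus side-chain-inclusive measurements are distinguished. The channel
radius per bin is the minimum atom-centre radius minus an explicit probe
allowance (default 1.4 Å), floored at zero — channel diameters are
method-dependent, so the probe is part of the output metadata.
`strand_radius_estimate` reads the shaft radius off a profile as the
smallest per-bin mean among well-populated bins (≥ half the fullest bin's
occupancy); sparse edge bins are excluded because their means are
noise-dominated.

**Hydrogen bonds** use a geometric criterion, not an energy function: a
census needs N···O ≤ 3.5 Å (default) plus, when the amide H is inferable
from the preceding carbonyl and the Cα, an N–H···O angle ≥ 120°. Same- and
adjacent-residue pairs within a chain are excluded. Cα-only models are
supported by every operation except this one, which raises a
`CapabilityError` rather than returning an empty census. **Inward/outward
labelling** uses the radial component of Cα→Cβ (pseudo-Cβ constructed
opposite the backbone N/C bisector when absent); glycine is labelled
`undetermined`.

All operations are equivariant under rigid-body transforms of the input;
this is property-tested.

## Assembly biochemistry (`assembly_biochem`)

Oligomer order is the `k ∈ 1..k_max` minimising |observed − k·monomer|,
ties to the smaller k (parsimony); the reported |delta| is therefore at
most half a monomer. Percent deviations are reported to two decimals.
Densitometry assumes band intensity proportional to protein *mass*, so the
molar ratio divides intensities by molecular weight:
`r = (I_CPδ/MW_CPδ)/(I_CP/MW_CP)`; CP-δ occupies lattice positions in place
of CP, so copies per particle = `180·r/(1+r)` and fibers = copies/5. The
across-replicate mean and sample sd are reported; the estimator is
invariant to common intensity rescaling and monotone in the CP-δ band.

## Synthetic data (`synthetic_data`)

Generators are bit-reproducible given (seed, parameters) and every output
carries a truth record.

* `gen_repeat_sequence` plants strict units (`V/L · x x · V · x · y (E/D/N)
  y`) and relaxed-only units (anchors from {I,M,F}/{A,I}, loop middle from
  {Q,S,T} — hydrophobic but outside the strict classes, so strict scans
  cannot extend into them). Spacer/linker/tail residues are drawn from
  {G,S,T,N,Q,P}, which contains no anchor-class residue, so no unplanted
  window can match in either mode; the coiled-coil stub uses the heptad
  `LAALQSA`, which contains no charged residue and therefore no loop-flank
  hit. Relaxed repeats are laid out in runs of ≤ 4 separated by 8-residue
  linkers — the repeats are known to be separated by loops of various
  lengths, and this layout places 11 relaxed segments across a 104-residue
  region (88 repeat + 16 linker residues), matching the annotated second
  bracelet region exactly.
* `gen_pentamer_coords` builds five chains related by exact 72° rotations
  about ẑ. Strand Cα lie on a cylinder *geodesic* of the planted radius
  whose tangent makes the planted tilt with the axis — so every strand atom
  sits at exactly the planted radius, at the cost of a small chord bias
  (≤ ~0.6° over the tested grid) when a straight line is fitted to the
  slightly curved strand. The Cα spacing along the strand is compressed
  (1.5 Å) to keep that bias small; the fixture is an idealized geometric
  object, not a physical backbone. Repeats are identical templates offset
  axially by the rise, so centroid spacing equals the planted rise exactly
  before noise; loops sit at the loop radius in the axial gap between
  strand stacks, so strand and loop rings are separable by z. The optional
  pseudo-backbone (N, C 1.2 Å along the chain direction, O offset radially)
  exists purely so the H-bond census has atoms to count and is labelled
  non-physical in the truth record; optional Cβ atoms can be planted
  radially inward or outward for labelling tests.
* `gen_mass_peaks`, `gen_gel_intensities` (inverse-then-forward of the
  stoichiometry formula with mean-preserving log-normal noise at the given
  CV) and `gen_em_lengths` (Gaussian, truncated at zero by redraw) are
  simple parametric emulations of the corresponding measurements.

What passing these tests shows — and does not. Planted-repeat recovery
shows the scanner is exact on sequences whose flanks match nowhere; real
flanking domains can contain chance matches, which is what `min_run = 2`
is for. Geometry recovery shows correctness of the measurement operators
on near-ideal C5 objects with isotropic noise ≤ 0.3 Å; real crystal
structures add anisotropic error, missing residues and genuine asymmetry.
The stoichiometry simulation shows estimator calibration under the assumed
log-normal intensity noise, not under real blotting nonlinearities.

## Problem sizes and numerical choices

The test suite and the acceptance script use 5-repeat pentamers (200
residues), ≤ 346-residue sequences, a 3×3×3 (rise, tilt, radius) recovery
grid at σ = 0.3 Å with per-cell fixed seeds, 3 densitometry replicates at
30% CV and 200-length EM samples — sizes chosen to match the study's own
object sizes while keeping every stage effectively instantaneous.
Tolerances: recovery within 5% (rise), 3° (tilt), 0.5 Å (radius), 1° (C5
angle); brute-force oracle agreement is exact on sequences ≤ 60 aa.
Degenerate inputs fail loudly (empty sequences, < 2 repeats for a rise,
Cα-only H-bond censuses) or are reported as absent (sd of a single
spacing, statistics of an empty length sample), never silently guessed.

## Known limitations

* The scanner is a deterministic consensus, not a profile model; it does
  not score partial matches into runs and cannot learn virus-specific
  preferences at x positions.
* The relaxed-region layout of real δ sequences (how many segments, where
  the variable loops fall) is reported as scanned runs with unlabelled
  gaps; the package does not force a fixed segment count onto a region.
* Heptad stutters are localised only up to the window between flanking
  a/d hydrophobics (see above).
* The H-bond census infers amide H positions geometrically; on
  non-physical pseudo-backbones the census counts contacts, not real
  hydrogen bonds.
* Fiber bending and per-particle copy-number variation are out of scope;
  the stoichiometry estimator returns a lattice-level average.
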