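# Methods

## Problem and model

A transmembrane segment (TMS) is a contiguous residue range that crosses the
lipid bilayer once; a re-entrant region enters and exits the membrane on the
same side and is not a TMS. Membrane-positioning tools optimise the placement
of a rigid structure in an implicit membrane and report the embedded segments
together with the two boundary surfaces — two parallel planes (planar
membranes) or two concentric spheres (curved membranes). On predicted models
that raw output needs correction: flexible linkers and low-confidence regions
distort the placement, broken helices are reported as two segments, and some
crossings are missed entirely. This package implements the correction
pipeline, the PAE-based domain partition that feeds the per-domain placement
track, the reference-mapping procedure and the multi-source comparison
statistics.

All residue coordinates are 1-based closed intervals, matching the UniProt
TRANSMEM rendering that the comparison module consumes. Membrane sides are
abstract labels (`side1`/`side2`); only equality of ordered
(entry, exit) pairs — "same orientation" — is ever used.

## Domain partition

The partition treats the predicted aligned error matrix as evidence of rigid
mutual arrangement: a residue pair with PAE below 12 Å is a "low" pair. For a
candidate split of a segment at site *s*, D_intra is the low-pair fraction
pooled over within-left and within-right pairs (i < j), and D_inter the
low-pair fraction over left×right pairs. Design choices the definition leaves
open, resolved here:

- **Pooling.** D_intra pools the two halves into a single fraction rather
  than combining two per-half densities; pooling is the simplest reading that
  yields one number per site.
- **Asymmetry.** Exported PAE matrices are asymmetric; a pair's error is the
  minimum of the two directions.
- **Degenerate ratios.** D_inter = 0 with D_intra > 0 gives ratio +∞ (passes
  any threshold); 0/0 is treated as failing.
- **Admissible sites.** Each half must keep at least `min_fragment_len` (30)
  residues. Unbounded sites would allow 1-residue fragments whose densities
  are meaningless; 30 residues is roughly the smallest autonomously folding
  unit. Configurable.
- **Ties** break to the smallest site index.

A segment longer than 500 residues is split when the best ratio reaches 20
(length 500–1000) or 10 (length > 1000); recursion is depth-first,
left-first, and stops when every segment is ≤ 500 residues or no admissible
split passes. Per-site densities are computed from 2-D prefix sums of the
boolean low-PAE matrix, so a full scan of a segment costs O(L²); the test
oracle recounts each site directly from matrix slices.

## Preprocessing

Annotated signal and mitochondrial transit peptides (caller-supplied ranges;
the package does not fetch annotations) and residues with pLDDT below 50 are
removed before placement. Confidence is stored on the 0–100 scale; files
using the 0–1 convention are detected (all temperature factors ≤ 1) and
rescaled on read. Removal never renumbers: trimmed models keep numbering
gaps, so TMS coordinates from any track are directly comparable. Stripping
and trimming commute, so their order is immaterial.

## TMS correction rules

- **Classification.** Each raw segment is widened by 10 residues per side
  (in numbering space, using only residues that exist after trimming). Over
  all main-chain atoms (N, CA, C, O) in the window, the minimum distance to
  each boundary is computed; both < 10 Å ⇒ transmembrane, else re-entrant.
  Re-entrant segments are excluded from the TMS track before merging and
  recovery, but retained on a separate output track.
- **Merging.** Adjacent same-orientation TMSs separated by fewer than 10
  residues merge, repeated to fixpoint (a merged segment may reach its next
  neighbour). The operation is idempotent.
- **Recovery.** Adjacent same-orientation TMSs separated by ≥ 15 residues
  imply an odd number of missed crossings; exactly one is recovered per gap.
  The centre is the gap residue with the smallest |d1 − d2| over its
  main-chain atoms (ties to the smaller residue number); the recovered TMS is
  the centre ± 5 residues ("up to 10 residues around it" read as a symmetric
  window, configurable via `missing_halfwidth`), clipped against both flanks,
  with the reversed orientation of the flanks — topologically forced, since
  an odd number of crossings must separate two same-orientation TMSs and one
  is inserted. Gaps whose residues lack coordinates are skipped with a
  logged warning.
- **Combination.** The full-model and per-domain tracks are united; a
  domain-derived segment overlapping a full-model segment by ≥ 10 residues is
  the same crossing and the full-model boundaries win; remaining overlapping
  survivors merge to their union span. No published rule pins this
  combination down; union-prefer-full is this package's documented choice.

## Reference mapping

Hits below or at 95 % identity are discarded (strict bound). Projection is by
constant offset for ungapped hits; when aligned sequences are present, a
per-column walk maps subject to query positions across indels. Projections
partially outside the hit span are clipped rather than discarded when at
least one residue survives — at > 95 % identity the difference is marginal
and clipping preserves signal. Projected ranges are clustered by single
linkage (link = overlap ≥ 10 residues; union-find over all pairs, validated
against a transitive-closure oracle) and each cluster is reduced to the
floored median of starts and of ends (even counts: floor of the midpoint
average).

## Comparison

Matching between two TMS lists is a greedy one-to-one pairing by descending
overlap (ties to the earlier start); sources are consistent when every range
on both sides is paired with overlap ≥ 10, which implies equal counts. The
bijective reading was chosen over mutual coverage because it is stricter and
keeps counts comparable across sources; two empty lists are vacuously
consistent. Three-way categories: AUH when all three pairs are consistent,
the pair label when exactly one is, A\U\H when none is. Pairwise matching is
not transitive; the rare two-consistent-pairs case receives the
lexicographically first consistent-pair label and is logged.

## Synthetic fixtures

The generators emulate exactly the geometric and combinatorial features the
rules consume, with seeded determinism:

- **Helical bundles**: residues on an ideal helical curve (axial rise 1.5
  Å/residue, radius 2.3 Å, 100°/residue) crossing a planar slab (default
  thickness 30 Å, so each crossing is 20 residues) alternately, with 8-residue
  caps and 8-residue loops outside the slab; main-chain atoms are placed on
  the curve around each CA — sufficient for every distance computation under
  test, with no backbone-dihedral realism. Residues sit half a rise off the
  boundaries so none lies exactly on a plane.
- **Re-entrant hairpins**: a chain climbing to a configurable depth (default
  12 Å, keeping ≥ 10 Å from the far boundary) and descending on the same
  side. This generator exists because planted hairpins are needed to exercise
  the re-entrant branch of the classifier.
- **Block PAE matrices**: symmetric block-diagonal matrices (intra 4 Å,
  inter 20 Å, diagonal 0) with a seeded fraction of pairs flipped across the
  12 Å line.
- **Perturbed placements**: planted crossings dropped (missed TMS) or broken
  into two sub-segments around a jittered midpoint (kinked helix).
- **Perturbed annotation sets**: per-source shifts (seeded sign), drops and
  spurious additions on a shared truth, so each protein's three-way category
  is computable in closed form.

Spherical geometry is exercised directly through the distance function (a
slab wrapped onto a large sphere is geometrically equivalent for the rules
under test). What the fixtures do **not** model: AlphaFold's actual error
statistics, sequence realism, curved membranes in the placements, or the
correlated failure modes of real placement tools — passing tests demonstrate
that the correction rules implement their definitions exactly on controlled
geometry, not that the end-to-end annotations reach any particular accuracy
on real proteomes. Proteome-scale claims would additionally require database
snapshots and full model/placement runs, which are out of scope.

## Problem sizes and numerics

The acceptance measurements use 100 seeded block matrices (L ≤ 1200) for
split-oracle agreement, 200 for partition invariants, 10 structural fixtures
× 20 rigid transforms (tolerance 1e−6 Å on invariance) for classification,
200 random segment lists for merge-oracle agreement, 50 delete-one-crossing
replicates for recovery, 200 random range lists for clustering, a 20-protein
planted comparison fixture, and the standard 4-helix end-to-end fixture —
sizes chosen so every property is measured at meaningful multiplicity while
the whole suite completes in well under a minute per criterion on one CPU.

Numerical conventions: membrane normals must be unit length (tolerance
1e−9); all distance comparisons are strict inequalities as stated; all
tie-breaks go to the smaller residue/site index; randomness enters only
through explicit integer seeds (NumPy `default_rng`), making every output
bit-reproducible.

## Known limitations

- Recovery inserts at most one TMS per gap; a gap hiding three or more
  crossings (same-orientation flanks again) is under-corrected.
- The classifier trusts the upstream placement's embedded segments; a
  crossing the placement tool never reported anywhere in the chain and that
  has no same-orientation flanking pair cannot be recovered.
- Offset projection assumes near-ungapped hits; hits with indels must carry
  aligned sequences or are rejected rather than approximated.
- The raw report dialects of placement tools vary; the package defines its
  own versioned placement schema and consumes that contract.
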