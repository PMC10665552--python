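# Methods

## The decoding model

A combinatorial-barcode FISH experiment images each field of view (FOV)
over R barcode rounds; in each round a transcript appears as one
diffraction-limited spot whose pseudo-color is one of P symbols. The
codebook maps each gene to a length-R color vector with pairwise Hamming
distance ≥ d between genes. With d = 3 the closed distance-1 balls around
codewords are disjoint, so any single corrupted or missing round can be
corrected unambiguously — this is the error model the whole pipeline is
built around. Defaults are R = 4 and d = 3; P is free (a physical
hybridization schedule of many imaging cycles across a few fluorescence
channels folds into this abstract (round, pseudo-color) grid, and how
cycles map onto rounds is configuration, not algorithm).

Decoding proceeds per FOV and per *seed* round:

1. **Pass 1 (exact).** Each seed-round spot is combined with its nearest
   neighbour (Euclidean, closed ball of radius 1.2 px) in every other
   round. The combination is accepted only if it is *mutual* — every
   member's nearest seed-round spot is the anchor — and its color vector
   equals a codeword exactly. Mutuality makes accepted combinations
   provably disjoint, so pass 1 is computed on a snapshot and is
   order-independent. Accepted spots are consumed.
2. **Pass 2 (rescue).** For each remaining seed-round spot, all
   assignments of at most one remaining neighbour per round (a round may
   be left missing) are enumerated. A missing round counts as one
   mismatch. Assignments whose vector lies within Hamming distance 1 of a
   *unique* codeword compete; preference is (a) more rounds present, then
   (b) minimum summed pairwise distance among member spots, then (c) the
   lexicographically smallest member-id tuple. If the minimum is shared
   by two different genes the anchor is ambiguous and dropped — ties are
   never broken arbitrarily. Accepted spots are consumed immediately (in
   spot-id order); spots of dropped anchors stay available until the pass
   ends.
3. **Consensus.** Steps 1–2 run once with every round as seed. Calls from
   different seeds are merged when they name the same gene and share at
   least one member spot — the weakest relation that identifies per-seed
   duplicates of one physical transcript. A merged transcript's
   coordinate is the centroid of the union of its member spots, and it is
   retained when at least `min_seeds` seeds support it.

`min_seeds` defaults to 4 (retain only genes called by *more than three*
of the four seeds, read literally). Note what 4-of-4 implies: a transcript
that lost a round to dropout cannot be seeded from that round, caps out at
3 seeds and is discarded, whereas a transcript with a *corrupted* round
still supports all 4 seeds (the corrupted spot itself can anchor a rescue).
`min_seeds = 3` keeps single-dropout transcripts recoverable and is what
the error-correction analyses here use; the choice is a prominent
parameter, not a constant.

### Determinism and numerics

- All neighbour queries use the closed ball (a spot at exactly 1.2 px is a
  neighbour); ordering is by (distance, spot_id) everywhere, so results do
  not depend on floating-point luck beyond the distances themselves.
- Spatial search is dense vectorised distance computation per round pair.
  At the per-FOV spot counts this package targets (10² – 10⁴ spots) this
  is faster and simpler than a spatial index and trivially identical to
  the brute-force definition the tests enforce.
- If a spot table has no `spot_id` column, canonical ids are assigned by
  sorting rows on (round, color, x, y, intensity); decoding output is
  therefore invariant to input row order.
- Pass-2 enumeration is exhaustive; a guard truncates per-round neighbour
  lists to the nearest 8 only if a pathological anchor would exceed 10⁵
  combinations (never reached under realistic densities).
- Two retained consensus transcripts of different genes can in principle
  share a spot (their per-seed calls are disjoint only within a seed).
  This is resolved deterministically in favour of higher seed support,
  then lower summed pair distance; the situation is essentially absent in
  practice but must not be left to chance.

## Codebook construction

Greedy scan over a seeded shuffle of the full P^R enumeration, keeping
each word at distance ≥ d from all kept words. Greedy codes are maximal
but not always maximum, so a pass that falls short of the requested size
restarts with a fresh shuffle from the same seeded stream (up to 50
restarts) before reporting a capacity error naming the best achieved
count. This finds, e.g., the full 9-word ternary R = 4, d = 3 code and
codes of ≥ 50 words over P = 12 reliably, while staying deterministic per
seed.

## Probe design

- **Primary probes**: every 28-nt window of a gene's exonic sequence is a
  candidate; melting temperature is computed with unified nearest-neighbor
  thermodynamics (SantaLucia 1998 parameters, via Biopython's `Tm_NN`) at
  50 mM monovalent salt and 250 pM per-strand concentration — the bounds
  [50, 80] °C are the constraint of record, the conditions are
  configurable and recorded. Bounds are inclusive ("range from X to Y").
- **Off-target screen**: a candidate is removed if any of its 17-mers
  occurs in any other gene, on either strand. Exact k-mer matching is the
  implemented decision rule (it stands in for a local alignment search;
  gapped or mismatched hits are out of scope by design).
- **Selection**: greedy left-to-right choice of non-overlapping windows,
  optimal for equal-length interval scheduling, capped at 32; genes
  yielding fewer than 17 are rejected and reported with the achieved
  count, never silently dropped.
- **Readouts**: random sequences (default 20 nt — the length is a free
  design choice) accepted when GC ∈ [0.40, 0.60] and no 10-mer on either
  strand collides with the reference index or a previously accepted
  readout. Both the reference screen and the pairwise screen are
  individually switchable since protocols differ on whether orthogonality
  is checked against a genome, the pool, or both.

## The simulator: what it emulates and what it does not

The generator produces multi-FOV tissue with non-overlapping circular
cells on a jittered grid, per-cell per-gene Poisson counts, uniform
within-cell transcript placement, and spot tables carrying the four
corruption processes the decoder must survive: isotropic Gaussian jitter
per spot, independent per-spot dropout, uniform false spots (spatial
Poisson), and rigid per-round shifts. Images are clean Gaussian PSFs on a
constant background with optional additive noise.

It deliberately does **not** model optical aberration, channel
bleed-through, autofluorescence, spatially varying background, cell-shape
irregularity, transcript clustering within cells, or 3-D structure.
Passing tests therefore demonstrate algorithmic correctness under the
stated statistical model, not performance on raw microscope data — on real
data, detection quality and segmentation accuracy dominate, and both enter
this pipeline as inputs. One master seed fans out into named substreams
per stage, so e.g. the dropout pattern is reproducible independently of
jitter.

Default study conditions used by the test suite and acceptance script:
50-gene codebooks (R = 4, P = 12, d = 3), 4 FOVs of 512×512 px, 50 cells
per FOV, ≈ 200 transcripts per FOV; robustness runs use 500 transcripts at
σ = 0.25 px jitter on a ≥ 5 px grid, 1000 transcripts at 10 % dropout,
and 100 isolated transcripts for single-error rescue. These sizes give
binomial error bars tight enough for the stated bounds while keeping any
single run in the seconds range.

## Registration and detection stand-ins

Registration is restricted to translation, estimated by upsampled phase
cross-correlation against the round-0 nuclear image; rotation and scale
are out of scope (drift between rounds at a fixed stage position is
translational to first order). Spot detection is a classical
Laplacian-of-Gaussian detector with center-of-mass sub-pixel refinement:
it honours the decoder's spot-table contract and is the documented
substitute for learned detectors, whose output semantics cannot be
reproduced without their weights. Image denoising and PSF deconvolution
are likewise not implemented — the simulator renders clean images, so the
detector is exercised on the model it assumes.

## Quantification

Transcripts are assigned to the mask label under their rounded pixel;
background stays in an explicit unassigned list so counts are conserved.
Duplicate cells in FOV overlaps are matched by global centroid distance
(default radius: one cell radius; the protocol gives no threshold) and
resolved by removing the member with fewer transcripts, ties broken
against the higher-numbered FOV; pairs are processed in ascending
(distance, id) order, making the retained set order-independent.
Neighbour smoothing x′ = (1 − α)·x + α·mean(k-NN profiles) is provided but
off by default (α = 0): the weighting is described only as an optional
enhancement, and its exact form is this package's own stand-in.

## Scoring

S = F ⊙ M is necessarily elementwise: both factors are cell-type × gene,
so no other product is dimensionally possible. "Expressed" means value
> 0; the ≥ 20 % filter is inclusive. The Wilcoxon rank-sum test is
two-sided, each type against all other cells, exact for small untied
samples (scipy's auto method); completely tied samples are assigned p = 1
directly, since no separation evidence exists and the tie-corrected normal
approximation degenerates. The BH family is all (type, gene) pairs tested
in one call — callers who test in batches define their own family by
batching. Whether expression is raw or log-normalised is the caller's
choice; the operations are defined for any non-negative matrix.

## Known limitations

- Decoding guarantees are proven under the simulator's model; real-data
  performance depends on upstream detection and segmentation.
- The pass-2 preference for larger member sets over smaller ones (before
  distance) is one reading of "keep the point sets with the minimum
  distances"; the alternative (comparing distance sums across set sizes)
  penalises using all available evidence and differs only when a
  corrupted spot could be left out — the choice is documented here and
  fixed, not configurable.
- Codebook search is greedy-with-restarts, adequate at panel sizes of
  10²–10³; it makes no optimality claim near the true capacity of a code.
- The k-mer screens implement exact-match specificity only.
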