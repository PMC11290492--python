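# Methods

This note specifies the generative model, the analysis conventions, and
the numerical choices in `baitjoint`, including what the simulator does
*not* attempt to model.

## Toy locus and genome

The locus chromosome `chrL` (40 kb) carries eight V segments with
RAG1/2 scission points every ~3 kb — five in deletional (DEL, '+') and
three in inversional (INV, '−') orientation — partitioned into four
sub-TADs (sTAD1-2 distal through sTAD5 J-proximal), and one J segment
('−', cut at 30,000) whose DSB carries two baits: `J1CE` (coding-end
side, primer downstream) and `J1SE` (signal-end side). `chrP` holds an
off-target receptor region with its own RAG cut site (label `RecA`,
cut at 5,000); `chrD` is a plain decoy chromosome for spontaneous
translocation partners. All coordinates are 0-based half-open
internally; the tlx dialect is 1-based inclusive at emission only.

**Flank guard.** Joint structure must be an emergent sequence property,
so chance identity between bait and prey flanks near cut sites is
excluded by construction: the 25 bp on each side of every cut is drawn
from complement-closed disjoint alphabets ({A,T} at the bait cut, {C,G}
at prey cuts). Each alphabet equals its own complement set and the two
are disjoint, so a bait base can never equal a prey base in any join
orientation; the property is re-verified by exhaustive scan (all window
pairs, both orientations, every register) after genome construction.

## Generative model

Each read pair is one repair event drawn from
{V-J joint, bait rejoin, translocation, unjoined} with configured
rates. Unjoined molecules yield the germline bait sequence. V-J events
choose a sub-TAD by usage weight, a segment uniformly within it, and a
prey end: the bait-cognate end (CE prey for the CE bait) or, with the
hybrid rate, the other end. Translocations split into receptor-locus
events (junction at the `RecA` cut) and spontaneous events (uniform
random position and strand on `chrD`).

Each end loses `r ≥ 0` bases to resection, modeled as a point mass
`w0` at 0 plus a truncated geometric tail (mean 20 bp, truncated at
100 bp). Joint structure is drawn from configured weights over
{direct, MH k, insertion m} (k, m ≤ 20).

**Sequence-exact placement.** A requested structure is realized only
where the reference supports it. For each (bait line, prey line) pair,
a base-match matrix over read-oriented flank strings yields, for every
(bait resection β, prey resection ρ) cell, whether a given structure
can exist there: an MH of length k needs k consecutive matches
spanning the junction and mismatch runs of length 3 (the caller's
termination horizon, `max_mismatch + 1`) on both sides; a direct joint
needs the two mismatch runs only; an insertion of length m needs
off-register mismatches so extension cannot bridge it. The junction is
placed at the nearest feasible cell, preserving the drawn prey offset
ρ whenever any bait offset is feasible in its column (search order:
|Δρ| first, then |Δβ|, positive before negative) — prey offsets are
what all resection metrics measure, bait offsets enter no metric.
Insertion content is sampled excluding bases that would extend either
alignment; palindromic insertions (reverse complement of the
bait-proximal flank, a P-nucleotide analogue) are produced at a
configured rate for the CE bait when compatible.

Two consequences are inherent to emergent structure and are handled
explicitly rather than hidden:

* **MH joints move.** An MH k exists only where a k-mer is shared, so
  an MH junction drawn at the cut is displaced to the nearest register
  where the homology exists. Direct and insertion joints preserve their
  drawn offsets exactly (the guard guarantees feasibility at the cut).
* **Degradation ladder.** A context may contain no register for a
  requested length anywhere (exact k-mer co-occurrence is Poisson-rare;
  e.g. one segment/end context has no MH4 register under genome seed 0).
  The simulator then degrades deterministically MH k → k−1 → … →
  direct (likewise for insertions) and records the realized structure
  in truth.

Because placement is deterministic, the model-implied resection
enrichment is computable in closed form:
`expected_resection_enrichment` enumerates, for every (segment, prey
end, structure) context, the map from drawn to realized prey offset,
integrates the resection mixture over it, and weights by V usage,
hybrid rate, and structure weights. Simulated libraries are compared
against this exact expectation, not against the raw mixture.

Ground truth per read records event class, prey identity, end type,
configuration, realized structure (with palindromic flag), measured
bait and prey offsets (strand-normalized, negative into the coding
body), and the tlx record of the clean molecule. Substitution errors
(uniform per base) are applied to emitted reads only; optional
duplicates re-emit the previous molecule under a new read name.

## Calling and classification

The caller matches the bait primer at the read start (≤ 2 mismatches),
extends greedily toward the DSB under a total mismatch budget of 2
(trailing mismatches trimmed, so three consecutive mismatches always
terminate extension at their start — the property the placement
horizon guarantees), then seeds the remaining suffix with exact
20-mers against both strands of the reference and keeps the longest
ungapped extension (ties: leftmost on query, lowest reference
coordinate, '+' strand). A prey alignment continuing the bait's own
diagonal is the germline signature and yields no call. Junction
coordinates follow the tlx convention: `Junction` is the strand-aware
first prey base, `B_Junction` the junction-proximal bait end.

Classification is purely coordinate-based. Structure derives from the
query overlap `B_Qend − Qstart + 1` (positive = MH, zero = direct,
negative = insertion). Category uses the junction point: bait region →
rejoin; ±200 bp of a V cut → V-J; locus interval → other intra-locus;
otherwise translocation (receptor region vs spontaneous). CE/SE is the
majority flank of the prey alignment relative to the cut (ties resolved
toward the junction and flagged). The resection offset is the junction
boundary minus the cut, sign-flipped for '−' segments so negative
always points into the coding body. The string oracle re-derives
structure from the read sequence by maximal re-extension of both
alignments and is used in tests to certify the coordinate arithmetic.

## Metrics conventions

* Normalization depth 500,000 read pairs (uniform downsampling without
  replacement; smaller libraries are used whole with a warning).
* Structure distribution over 41 bins (MH20…1, direct, INS1…20);
  longer events are tallied out-of-range separately. MMEJ = MH > 1 bp.
* Resection enrichment = N(|d| ≤ 10) / N(|d| ≤ 100) over V-J prey
  offsets; undefined (reported as such) when the denominator is empty,
  as is the CE/SE ratio when no SE junctions exist.
* Translocations: relative frequency = raw junction count scaled to
  500,000 read pairs, no deduplication; absolute count deduplicates on
  (Rname, Strand, Junction, B_Junction).

## Numerical and determinism choices

All randomness flows through `numpy.random.Generator(PCG64(seed))`;
derived seeds stay below 2³¹. Categorical draws use inverse-CDF lookup
on precomputed cumulative weights. Feasibility matrices are boolean
NumPy arrays built from vectorized diagonal comparisons of the two
flank strings (101 × 101 cells per structure per context, cached per
context). Outputs are plain text with stable column orders, so equal
seeds give byte-identical files.

## Limitations (by design)

The generator is a controlled testbed, not a sequencing emulator: no
indel errors, quality-score variation, adapter/chimera artifacts, or
PCR-bias beyond the optional exact-duplicate model; resection is
independent on the two ends and structure is drawn independently of
resection (before placement coupling); the toy genome is short and
repeat-free, making the caller's exact-seed alignment near-perfect by
construction; translocation partners are limited to one receptor site
and one decoy chromosome; and hairpin-opening chemistry is summarized
by the palindromic-insertion rate rather than modeled mechanistically.
No biological claims are made from these simulations; all numbers in
the README are properties of this model computed by this package.
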