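# Methods

This note documents the models, conventions and design choices behind each
analysis, what the synthetic generator does and does not emulate, and the
known limitations.

## Annotation model

Coordinates are 1-based inclusive on the majority strand; a feature crossing
the origin is stored with a `wraps` flag and its post-origin end (CR1
`15020–15333+175` → start 15020, end 175, wraps).  Both the `+N` suffix of
printed tables and GenBank `join(x..L,1..y)` locations normalize to this one
representation.  Lengths are `end − start + 1`, or `(L − start + 1) + end`
for wraps.  Control regions are first-class features: they participate in
ordering and intergenic accounting because published gene tables list gaps
into and out of them.  Declared sizes from input tables are never discarded;
`MitoAnnotation.validate()` reports any disagreement with the computed
lengths.  GenBank names map to canonical symbols (nad1…nad6/nad4l, cox1–3,
atp6/8, cytb, rrnS/rrnL, trnX) through an editable TSV synonym table,
because deposited records are wildly inconsistent.

The bundled reference fixture is the published *T. palmi* table: all 39
computed lengths equal the printed sizes, and the printed IGN column is
reproduced exactly by the ledger arithmetic.  Its wrap junction (CR1 ending
at position 175, nad5 starting at 176) closes the circle with a gap of 0;
the ledger marks that entry `wrap_junction` so the closure is auditable.

## Composition and skew

`AT skew = (A−T)/(A+T)`, `GC skew = (G−C)/(G+C)`; both are scale-invariant,
so printed percentages and raw counts give identical values.  Partitions use
each member feature's majority-strand *span*, not its coding orientation:
skews are statements about strand asymmetry, and mixing orientations would
erase the signal the statistic exists to measure.  Within a partition each
genomic position is counted once (`total_bp`), but the sum of member
lengths is also reported (`member_bp`) because published size columns count
overlapping positions once per feature — on the reference layout the tRNA
partition is 1,393 bp by member lengths and 1,388 bp by unique positions
(5 bp of tRNA–tRNA overlap).  N bases are tallied separately and excluded
from percentage and skew denominators.  Report tables round half-up to 2
decimals, matching the convention of the published tables; JSON output keeps
full precision.

## Codon usage and RSCU

Genetic code: NCBI translation table 5 (invertebrate mitochondrial; 62
sense codons, stops TAA/TAG only; AGA/AGG = Ser, ATA = Met) — overridable
per call.  Minority-strand genes are reverse-complemented before counting:
codon identity is reading-frame semantics, unlike the composition
partitions.  Terminal TAA/TAG are excluded from usage counts by default and
trailing incomplete-stop remainders (T / TA) are never counted; both totals
(with and without stops) are recoverable by flag because published codon
totals rarely state their convention.  RSCU is observed count divided by
the family mean; a family with zero total reports all zeros rather than
NaNs.  Ties in "most frequent codon" reports break alphabetically.

## Ka/Ks (Nei–Gojobori with Jukes–Cantor correction)

Site counting follows the 1986 method: each codon position contributes the
fraction of its single-nucleotide changes that are synonymous, with changes
to stop codons excluded from the denominator, so S + N = 3 per codon
exactly.  Codon pairs differing at d positions average their synonymous /
nonsynonymous difference counts over all d! orderings with equal weight;
orderings that pass through a stop codon are excluded, falling back to the
unrestricted average in the (rare) case that every ordering is blocked.
S and N are averaged over the two sequences; pS = Sd/S and pN = Nd/N are
corrected by K = −(3/4)·ln(1 − (4/3)p).  A proportion ≥ 3/4 is reported as
saturated/missing; Ks = 0 yields a missing ratio, never an infinity, and
missing ratios are dropped from per-gene means.  Codon columns containing
gaps or N, or a stop codon in either sequence, are dropped pairwise.

Alignment is an input, not a responsibility: `check_aligned` only enforces
equal, codon-sized lengths.  This counting method is the classic lineage of
the statistic as implemented in standard polymorphism tools; exact numeric
agreement with any particular GUI program is not a design goal.

A subtlety worth knowing: pathway averaging attributes fractional
nonsynonymous differences to codons that experienced two *individually
synonymous* hits at different positions (e.g. CTT→CTA→TTA, all Leu, where
the other ordering passes through Phe).  A simulation in which every event
is synonymous therefore yields Ka exactly 0 only while codons carry at most
one hit; at realistic divergences Ka is tiny but nonzero.  The exactness
tests use single-hit constructions; the simulation tests assert amino-acid
identity and a near-zero Ka.

## IGN ledger

`ign(i) = start(i+1) − end(i) − 1` for consecutive features in positional
order, the last pair closing the circle; strand is ignored (adjacency is
positional).  Spacers are positive entries, overlaps negative, and the
tiling identity `Σ lengths + Σ ign = L` holds exactly by construction —
it is asserted on the reference table (15,333) and on random synthetic
genomes.  "Major" spacers are strictly greater than a threshold
(default 10 bp).  An overlap spanning more than half the genome aborts with
a "probably mis-sorted" error rather than producing nonsense.  Published
summaries of this genome disagree internally on the overlap count (11 in
the gene table and results text, 12 in the abstract); the ledger reproduces
the table-derived 11 and the discrepancy is noted here rather than hidden.

## Gene-order comparison

Orders are circular sequences of signed symbols (sign = strand relative to
the majority strand), CRs excluded by default.  Per-gene classification
uses two independent observations — strand flip, and retention of the
unsigned neighbour pair:

| sign      | neighbours retained | call                |
|-----------|---------------------|---------------------|
| unchanged | ≥ 1                 | conserved           |
| unchanged | 0                   | transposed          |
| flipped   | both                | inverted (in place) |
| flipped   | < both              | inverse_transposed  |

Judging retention on unsigned names keeps a gene conserved when only its
neighbour flipped; requiring just one retained neighbour keeps the flanks
of a moved gene conserved (they keep their other neighbour); requiring both
for "inverted" ensures a flipped gene that also moved is called
inverse-transposed even when it happens to re-acquire one old neighbour
(as rrnL–trnV does against the ancestral order).  This is a defined
positional proxy for scenario-derived event labels: heuristic scenario
reconstruction (common-interval / TDRL search) is deliberately out of
scope because its scenarios are non-unique, and the proxy may disagree
with a scenario label for genes at block boundaries.

Breakpoints count query adjacencies absent from the reference in both
readings ((a,b) and (−b,−a)); the count is symmetric and
rotation-invariant, and zero iff the circles agree up to rotation (or
whole-molecule reflection, which is the same molecule read from the other
strand).  Shared blocks are maximal runs of ≥ 2 genes whose successive
signed adjacencies are all preserved, reported in query orientation; sign
consistency makes mixed-orientation chains impossible.

## Control regions

Element names are conventional but detection thresholds are not published,
so every scan takes parameters with these defaults: polyT ≥ 5 T starting in
the 5′ quarter; [TA(A)]n ≥ 3 tandem TA/TAA units; TATA exact substring (all
occurrences); G(A)nT with 1 ≤ n ≤ 6 (all occurrences); GA-rich window of
≥ 10 nt with A+G ≥ 0.75, snapped to its A/G run and extended maximally
right; stem-loops with stem ≥ 5 bp, loop 3–20 nt, Watson–Crick pairs only
(DNA level, no G·U wobble).  Missing elements are reported missing, never
invented, and all scans are strand-explicit.  Hairpin search enumerates
every loop placement and extends arms outward maximally — quadratic, which
is irrelevant at CR sizes (≤ ~1 kb).  CR1/CR2 duplication uses exact local
(Smith–Waterman) alignment with match +1 / mismatch −1 / gap −2, flagging a
duplication at ≥ 50 aligned columns and ≥ 0.9 identity; exact DP is cheap at
these lengths, so no k-mer heuristics.

## Synthetic data

The generator's defaults are the modelled study conditions: the published
39-feature layout (lengths, strands, signed gaps — spacers 520 bp, overlaps
78 bp), whole-genome base probabilities (0.43, 0.11, 0.10, 0.36) for
(A, C, G, T) matching the printed composition, cox1 forced to a TTG start,
and an incomplete stop planted wherever the template length is not a codon
multiple (the 169 bp atp8 slot).  PCG bodies are drawn i.i.d. from sense
codons; because excluding the AT-rich stop codons would bias composition,
the per-base weights are first fitted (fixed-point iteration) so the
sense-codon mixture reproduces the target composition.  Everything is
deterministic for a fixed seed (numpy `default_rng`; no unordered
iteration).

Overlapping features are written in positional order with the later feature
winning the shared span.  Consequently a PCG's downstream junction — the
stop codon of a majority-strand gene, the start codon of a minority-strand
one — is not guaranteed where that junction lies inside an overlap; tests
check codon guarantees on overlap-free junctions.  Coordinate-level ground
truth (IGN ledger, gene order, tiling) is exact regardless.

Synthetic CRs lay their elements left to right from the 5′ end separated by
short C guards; filler is drawn from {A, C} (AT-rich like real CRs, yet
unable to base-pair with itself or to spell any motif containing T or G),
which guarantees each planted element is also the leftmost detectable one.

`evolve_cds` is an acceptance-thinning process, not a full codon model
(no GY94-style rate matrix, no transition/transversion bias, no indels):
uniform single-base proposals are accepted with probability 1 when
synonymous and ω when nonsynonymous, stop-creating proposals always
rejected, until `round(divergence × length)` substitutions are planted.
Because synonymous and nonsynonymous opportunities enter the acceptance
ratio the same way the site counter measures them, the Nei–Gojobori ratio
recovers ω to within a few percent at 10⁴ codons and divergence 0.1 — the
scale used by the recovery checks (ω ∈ {0.1, 0.5, 1.0} within ±25%).

Rearrangement operations act on the signed order: transposition moves a
contiguous block, inversion reverses it in place and flips signs, inverse
transposition does both, and TDRL duplicates a block in tandem and keeps
each gene from the first or second copy per a keep-pattern.  Ops apply left
to right; a non-contiguous or unknown block is an error.

What the generator does *not* emulate: real codon bias beyond base
composition, rate heterogeneity among sites and genes, tRNA/rRNA secondary
structure, indels, and sequencing error.  Passing tests therefore
demonstrate the correctness of the arithmetic and the estimators under the
stated generative model, not robustness to real-data artefacts such as
misannotation or alignment error.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the scales stated above:
full-size 15,333 bp synthetic genomes, 10⁴-codon Ka/Ks recoveries, 100
random tiling templates, exhaustive 62×62 codon-pair enumeration — chosen
as the smallest sizes at which the stochastic recoveries have comfortable
margins.  Report tables format floats at 2 decimals (half-up); JSON keeps
full precision.  Neutral classification of a Ka/Ks ratio uses a 1e−6
tolerance around 1.  Seeds are explicit everywhere; reruns are
byte-identical.

## Known limitations

- Ka/Ks assumes in-frame, already-aligned sequences; codon-aware alignment
  must happen upstream.
- The per-gene rearrangement labels are a positional proxy (see above).
- GenBank ingestion trusts the record's feature boundaries; there is no
  de novo annotation, tRNA structure prediction, or assembly.
- The CR duplication test reports the single best local alignment; tandem
  multi-copy similarity would need repeated masking.
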