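# Methods

`sdweaver` is a targeted iterative assembler for genomic regions rich in
segmental duplications (SDs), together with the simulator and
evaluation machinery needed to study it.  This note describes the model
and procedure, the parameters that matter, the numerical choices, and
what the synthetic data does and does not capture.

## Problem

An SD region contains several copies (paralogs) of a ≥1 kb unit at
>90–99.5% sequence identity.  Standard assemblers collapse such copies
into one sequence because reads from all copies look alike.  The copies
do differ at sparse single-nucleotide positions — *cis-morphisms*
(paralog-specific variants) — and reads long enough to span several of
them can be attributed to their copy of origin.  The assembler exploits
this: starting from a short *anchor* taken from unique sequence flanking
one copy, it repeatedly (i) recruits reads similar to the anchor,
(ii) clusters them by cis-morphism genotype and keeps the cluster
continuing the copy being assembled, (iii) assembles that cluster into a
contig, and (iv) extends the anchor with the contig suffix, until the
region is traversed.

## Pipeline

### Mapping (recruitment)

A minimizer index (canonical 2-bit k-mer codes hashed with a
splitmix64-style mixer; window minimizers) is built once over all reads
and held in memory.  Querying the anchor yields shared minimizers per
(read, strand); these are chained colinearly (longest increasing
subsequence in read coordinates after sorting by anchor position) and a
read is recruited when the chain's extent covers at least
`min_cov_frac` (default 0.5) of the anchor.  Defaults `k=15, w=10` are
the standard long-read indexing regime.  Recruited reads are
strand-normalized to the anchor.

### Clustering

Reads and anchor are homopolymer-compressed (HPC), suppressing the
dominant long-read indel error mode; an exact coordinate map lifts HPC
intervals back to raw coordinates.  Each recruited read is aligned to
the HPC anchor (edlib, infix mode) and kept only if the **whole**
anchor aligns at sufficient identity.  Two numerical details matter:

- *Identity inflation.*  With identity defined as
  1 − edits/alignment-length, the free-indel optimum between unrelated
  DNA reaches ≈0.58, not ≈0.45, because indels inflate the alignment
  length.  Genuine 15%-error reads score ≈0.85 in HPC space.  The
  full-span threshold is therefore 0.78, and it is enforced on each
  half of the anchor separately: a read overlapping only part of the
  anchor can reach a borderline overall identity once the aligner
  smears its missing portion, but its uncovered half drops to
  near-random identity.  This filter proved load-bearing — reads
  passing a whole-anchor-only threshold contributed tails from the
  wrong genomic position and could derail the assembly.

- *Cis-morphism threshold.*  A column is a cis-morphism when its
  second most common base frequency f₂ exceeds a threshold.  The
  threshold must sit above sequencing noise but below 1/n for n stacked
  copies, so it depends on technology *and* coverage.  In automatic
  mode (the default) the noise level is estimated from the pileup
  itself — the mean f₂ over all columns, since at realistic
  cis-morphism densities almost every column is pure noise — and the
  per-column threshold is that estimate plus 2.5σ binomial at the
  column's depth.  The estimate absorbs systematic artifacts
  (substitutions that merge homopolymer runs produce column-specific
  elevated noise) that a theoretical error-rate calculation misses;
  2.5σ rather than 3σ because a copy whose full-span representation
  dips — typical right after the anchor enters the duplicated unit —
  has its private sites hovering at the detection limit, and losing
  them costs tracking far more than the extra noise columns cost the
  partition.  Fixed thresholds (0.25 CLR-like, 0.10 HiFi-like) remain
  available.  At most `max_sites` (default 200) columns are kept,
  largest f₂ first.

Reads become genotype vectors over the retained loci.  The *similarity
graph* joins two reads when they share ≥ `min_shared` (3) jointly
covered loci at normalized Hamming distance ≤ `max_dist` (0.4); its
connected components are clustering *blocks*.  Each block is partitioned
by `n_sim` (100) randomized simulations: each recursively splits on a
randomly chosen admissible locus — binary, reads with the locus's
second base versus everything else (major base, sporadic error bases,
and missing calls all follow the majority branch, since error bases
would otherwise make every locus produce an inadmissibly small child) —
until no locus is admissible.  Two details keep the randomization from
chasing noise.  First, the locus is drawn with probability
proportional to its within-subset minority fraction squared: a locus
genuinely segregating inside the current subset has a far larger
minority share than an error-artifact column, so clean split paths
dominate the simulations.  Second, the winning simulation minimizes
the sum over reads of the Hamming distance to the nearest cluster
consensus **plus 1.5 × coverage per cluster**: the raw sum decreases
with every split, and a noise split (whose minority count grows with
block size and so clears any fixed floor) saves only about one
mismatch per carved-off read, while a genuine copy split saves one per
read per distinguishing locus.  A locus is admissible when both
children would keep at least `min_frac` × coverage reads, where
coverage is the *expected full-anchor-span* coverage (sequencing
coverage scaled by (mean read − anchor)/mean read), not raw sequencing
depth, because only full-span reads are clustered.  A final
nearest-consensus reassignment pass moves each read to its closest
consensus, repairing reads that erred at the very locus they were
split on.

Cluster selection is anchored: the primary criterion is the Hamming
distance (Laplace-normalized and binned at ~2% granularity, so
consensus noise counts as a tie) between each cluster's consensus
genotype and the anchor's own bases at the cis-morphism loci — the
anchor carries the committed copy's alleles, refreshed every iteration
at consensus accuracy, so the nearest cluster continues the same copy.
Ties fall to the number of reads shared with the previous iteration's
selected cluster, then cluster size; clusters smaller than `min_reads`
only compete when nothing larger exists.  In the first iteration
anchor distance is the sole criterion, as there is no previous
cluster.

### Assembly

The selected cluster's reads are truncated to their anchor alignment
plus `flank` (default mean read length / 2) downstream and a short
600 bp buffer upstream — everything left of the anchor is committed
already, so re-polishing it every iteration is pure overhead — in raw
coordinates.  Since every
read is already positioned on the anchor, no overlap-layout machinery
is needed: the draft is the anchor extended left and right by read
tails, polished by majority pileup voting.  The tail backbone is *not*
simply the longest overhang — all tails start at the anchor boundary,
so same-origin tails agree over their shared prefix (pairwise identity
≈0.7 for 15%-error reads) while a contaminant's tail is unrelated
sequence (≈0.45); the longest tail endorsed by at least half of the
other long tails is used.  Polishing (default 2 rounds) tallies, per
draft position, base/deletion votes and insertion votes from
edlib alignments of every truncated read, and rewrites the draft by
majority (insertions need support from more than half of the covering
reads; multi-base insertions resolve over successive rounds).  Draft
ends covered by fewer than `trim_frac` of the cluster's reads are
trimmed: single-read tails carry raw error rates.  The benchmark
configuration uses three polish rounds and `trim_frac` = 0.7 —
committing only bases covered by at least 70% of the cluster lifts
final contig quality by roughly 2 Phred points over the generic 0.5
default, at the cost of slightly shorter per-iteration extensions.

### Extension

The anchor is located in the contig by infix alignment (≥90% identity,
else the run terminates as lost-track).  The contig suffix beyond the
anchor (capped at `step_cap`, default mean read length / 2) is appended
to the growing assembly, and the anchor window itself is *refreshed*
with the contig's copy of it: the cluster consensus just re-polished
those bases at full interior coverage, superseding the version
committed earlier from a thinner contig end.  The new anchor is the
last `anchor_len` bases of the assembly (sliding window; the suffix
window bounds per-iteration cost).  After the loop one extra consensus
pass re-polishes the final window, since bases committed in the last
iterations would otherwise exit having been polished only at a contig
end.  Termination: no extension, too few reads, lost track, maximum
iterations, or an optional extension budget.

Bidirectional assembly runs the procedure on the anchor and on its
reverse complement and stitches the two at the shared anchor.

## Simulator

SD copies evolve on a tree: the root holds a random (or supplied) unit;
each child copies its parent with independent per-base substitutions at
a fixed rate (substitution to a uniformly chosen different base; no
indel or rearrangement operators).  Four topologies: flat (star),
bifurcating (balanced binary, optionally skewed), cascading
(caterpillar), random (random recursive tree).  The per-edge rate for a
target leaf-vs-root identity *i* at depth *d* is 1 − i^(1/d) (back
mutation neglected; exact at d = 1).

Leaf units are laid out on one collapsed contig between unique random
flanks; a unique random spacer (default 3 kb in the benchmark layout)
precedes every unit after the first, so each unit has its own
anchor-source sequence, mirroring a genome in which every copy sits in
unique context.  No flank or spacer shares any 21-mer with any unit
(regenerated on collision), making initial anchors unambiguous.

Reads: uniform starts, Normal(mean, sd) lengths truncated to [200 bp,
contig], sampled until total bases ≥ coverage × contig length;
reverse-complemented with probability 0.5; truth label = unit containing
the read midpoint.  Errors are applied per base at the configured rate,
split 60% substitution / 25% insertion / 15% deletion — a fixed,
configurable mix standing in for chemistry-specific profiles.

What the simulator does **not** emulate: position- and
homopolymer-dependent error profiles, chimeric reads, coverage bias,
tandem repeats and mobile elements inside SD units, structural
differences between copies (indels, inversions, CNVs), and quality
scores.  Passing benchmarks therefore demonstrate the phasing and
consensus machinery under idealized uniform noise, not performance on
real flow-cell data — in particular, real homopolymer-biased indel
noise would lower consensus quality at long runs, and real SDs carry
indel cis-morphisms this model never generates.

## Benchmark and evaluation

The benchmark suite holds ten evolutionary scenarios: flat with 2, 4
and 8 leaves; three bifurcating shapes (balanced 4, balanced 8, skewed
8); cascading with 4 and 8; two random trees with 10 leaves.  The
desk-scale preset — SD unit 20 kb, identity 99.5%, coverage 40×,
sequencing error 15%, reads 5 kb ± 1 kb, flanks 8 kb, spacers 3 kb —
runs the whole suite (66 leaf assemblies) in roughly 10–15 minutes on
one core.  A paper-scale preset (0.5 Mb contigs, 18 kb ± 3 kb reads) is
provided but slow.  Each leaf is assembled from the last 2 kb of its
preceding unique sequence, with an extension budget of unit length
+ 800 bp; the evaluated contig is the extension only (the anchor is
input, not assembly product).  The budget margin is sized so that a
full-length unit still covers ≥95% of its contig.

At this scale the benchmark configuration sets the cluster floor factor
`min_frac` to 0.5 rather than the generic 0.8 default: with ~5 kb reads
over a 2 kb anchor the expected full-span cluster is ~24 reads, and a
true split's minority side can dip to ~12 reads when a copy is
under-represented right after the anchor enters the duplicated unit, so
a 0.8 floor sits above the signal and blocks real splits (merging two
copies for an iteration and destabilizing cluster tracking); with the
noise-split penalty carrying the false-positive control, 0.5 keeps the
floor safely below genuine minorities.

Desk scale is a genuinely harder regime than the original one, not just
a smaller one: a 5 kb read spans ~2–3× fewer cis-morphisms than an
18 kb read, and the per-window signature distinguishing a copy from its
nearest sibling drops to ~5–15 loci against comparable noise.  Cluster
tracking across ~15–25 iterations per copy therefore fails
intermittently — a run swaps onto a sibling copy mid-way or commits a
blended consensus — which shows up in the benchmark as a sibling
resolved twice (one copy unresolved) or as a contig whose Phred quality
sits in the low-to-mid 20s instead of ≥29.  Two-copy scenarios, where
the signature is unambiguous, resolve both copies at Q ≈ 29–33 across
seeds; scenarios with 4–10 stacked copies resolve roughly half to
seven-eighths of their units with minimum Q in the 22–28 range.  The
acceptance script runs the suite with 10 kb units (the small end of
the desk preset range) to keep all 66 assemblies within a modest
compute budget; the acceptance test suite exercises the flat
two- and eight-copy scenarios at 20 kb units.

Evaluation assigns each contig to the truth unit whose alignment covers
≥95% of the contig at the highest Phred score Q = −10·log₁₀(1 −
identity), capped at Q = 60 for perfect alignments (the conventional
FASTQ ceiling); identity is 1 − edits/alignment-length.  Because the
aligner consumes the full query, unrelated contig overhangs smear into
a low-identity fringe rather than clean terminal gaps; coverage and
identity are therefore measured on the maximum-scoring local core of
the alignment path (+1 match, −2 edit — retaining stretches above ≈⅔
identity), the way a local aligner would report them.  Ties on Q break
by edit distance, then unit order, and are flagged ambiguous.  A
truth unit is resolved when at least one contig is assigned to it.  The
BAC-style rule declares a reference sequence resolved when the aligned
core covers ≥99.5% of *its* length.  Median Q uses linear interpolation.

## Numerical and performance notes

All pairwise alignment is banded edit-distance (edlib) with an edit
budget: 34% of the anchor for pileup alignment, 32% of the read for
polishing.  Genuine 15%-error alignments sit near 22% edits, so the
band costs nothing there while making the aligner several-fold faster
and — as a side effect — dropping junk and far-paralog alignments
outright instead of letting their low-quality votes reach the
consensus.  Homopolymer compression is vectorized and its coordinate
maps are cached per read across iterations; reads whose minimizer
chain covers less than 72% of the anchor are skipped before pileup
alignment, as they cannot be full-span.

## Degenerate inputs and determinism

Zero error and zero divergence reduce the pipeline to a plain targeted
assembler that reproduces the source region exactly (Q = cap).  A
region with no cis-morphisms yields one block, one cluster.  Empty
sequences are rejected at the boundaries; an anchor recruiting nothing
at the first iteration is a hard error.  All randomness (tree shapes,
mutations, flanks, reads, locus choices) flows from explicit integer
seeds through `numpy.random` SeedSequences keyed by (seed, iteration,
block); identical seeds give byte-identical outputs everywhere.

## Known limitations

- Substitution-only evolution: indel cis-morphisms, common in real SDs,
  are neither simulated nor called (HPC absorbs part of this class).
- The consensus is a majority pileup, not a partial-order graph; below
  ~10× cluster coverage its quality degrades quickly.
- Cluster tracking is greedy; a copy whose informative sites vanish for
  longer than one anchor length (local perfect identity between copies)
  can still be swapped for its paralog.
- The minimizer recruiter has no spaced seeds or frequency filtering
  and is sized for targeted regions (≤ a few hundred Mb of reads), not
  whole-genome indexing.
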