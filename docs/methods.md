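# Methods

## The structure

The node-centric de Bruijn graph of a read set is represented by three
components:

1. **Bloom filter** over the set S of solid canonical k-mers: m bits,
   h hash functions, false-positive rate F ≈ (1 − e^(−h/r))ʰ with
   r = m/n. h is the integer nearest r·ln 2 (minimum 1), which is the
   integer minimiser of F (verified by scan in the tests). At the
   optimal h, F ≈ 0.6185ʳ and m ≈ 1.44·n·log₂(1/F).
2. **Critical false positives** cFP = P∖S, where P is the set of
   canonicalised 8-extensions of S that the filter accepts. Membership
   `bloom(x) ∧ x ∉ cFP` equals `x ∈ S` exactly for every x in the
   extension set E; outside E the answer is unspecified, and every
   traversal is started from members of S so nothing outside E is ever
   queried. cFP is kept as a sorted array of 64-bit packed k-mers and
   searched binarily.
3. **Marking structure** for traversal progress: a hash table over
   *complex* nodes only (in- or out-degree ≠ 1). Nodes inside simple
   paths are visited exactly when their bounding complex nodes' ports
   are, so they are never stored. Each entry costs about 2k+8 bits:
   the k-mer plus an 8-bit mask with one bit per extension "port"
   (4 right bases, 4 left bases, in the node's canonical frame) and a
   touched flag. Port-level marks are what make seed-coverage checks
   exact; the node-level mark/is_marked operations sit on top of the
   same mask.

Sizing theory: total structure = n·(1.44·log₂(1/F) + 16·F·k) bits
(E[|cFP|] = 8nF entries at 2k bits each), minimal at F* = 2.08/(16k),
giving n·(1.44·log₂(16k/2.08) + 2.08) bits. The cFP share at the
optimum is a constant 2.08 bits/k-mer for every k. Reported byte
figures use binary GB (2³⁰ bytes), the convention under which the
formulas reproduce the reference figures (6.8 / 3.7 / 13.7 GB at
n = 2.4·10⁹, k = 27). The self-information lower bound is
log₂ C(4ᵏ, n), evaluated through log-gamma.

## Representation choices

K-mers are unsigned integers, 2 bits per base (A=0 < C=1 < G=2 < T=3,
leftmost base most significant), k ≤ 31 so that a k-mer — and the
(k+1)-mer naming an edge — fits a 64-bit word. Integer order equals
lexicographic order, so the canonical (strand-collapsed) form is
`min(x, revcomp(x))`. Values travel as plain ints / numpy uint64
arrays rather than wrapper objects; contracts that a typed wrapper
would enforce (e.g. the Bloom filter stores canonical k-mers only) are
documented at the call sites. Reverse complement is a masked bitwise
NOT followed by a 2-bit-group reversal (constant number of word ops).

The hash family is a seeded splitmix64-style finaliser producing two
base hashes, expanded to h positions by double hashing
(g_i = h1 + i·h2 mod m, h2 forced odd). The filter state is a
deterministic function of (seed, inserted set), independent of
insertion order. Uniformity is not proven, only measured: the test
suite checks empirical false-positive rates against the analytic
formula within three binomial standard deviations at n = 10⁵ for
r ∈ {4, 8, 11.1, 16}.

## Construction pipeline

*Counting.* The canonical k-mer multiset of the reads is hashed into
partitions on disk (raw uint64 records), then each partition is
counted in memory and filtered at the solidity threshold d (default 3;
d = 1 for error-free simulations). Peak memory is bounded by the
largest partition; the result — sorted, deduplicated, strictly
ascending — is independent of read order and partition count. Counters
saturate at 255, which is irrelevant for any d ≤ 255. Sorted ascending
order is what gives the deterministic on-disk node enumeration used by
both the cFP construction and contig seeding.

*cFP.* P is written to disk (sorted, deduplicated), then filtered
against contiguous partitions D_i of the sorted S, one partition and
one chunk of P in memory at a time, survivors rewritten sequentially
between rounds. The number of partitions is derived from a byte
budget; the output is identical for any budget (asserted in tests
against an in-memory brute force).

## Traversal

Traversal operates on *oriented* k-mers; membership tests
canonicalise. A contig is seeded at every uncovered *path start* in
the ascending enumeration of S: a node whose backward degree differs
from 1 in the chosen orientation, or whose unique predecessor is a
branching node. Interior simple-path nodes are never seeds, which
makes each coverage check O(1) against the marking structure instead
of a walk to the nearest complex node (that walk, done per seed, is
quadratic on a linear genome). All-simple cycles have no path start
and are recovered in a second pass that walks each candidate backward
with an amortising seen-set (the seen-set is transient bookkeeping of
the cycle sweep, not part of the on-paper structure).

Extension rules, applied left to right at each step:

* several forward neighbors → branches whose simple-path extension
  dead-ends in fewer than 2k+1 nodes are ignored (**tips**; the bound
  is strict, a 2k+1-node dead end is kept);
* a single continuation whose backward degree ≠ 1 (a convergence) or
  which is a junction already *touched* by an earlier traversal →
  stop, marking the entry port; entering would re-walk territory
  already reached from the other side;
* still-multiple branches → bounded BFS: frontier levels of at most
  20 nodes, at most 500 levels, success only when a level collapses to
  a single node. On success the lexicographically smallest base-string
  path through the region is spliced into the contig, the region's
  complex nodes are fully marked and the origin's ports into it are
  closed; a region containing an already-touched junction is not
  re-traversed. On failure the contig simply ends; the branches are
  picked up later as fresh seeds.

Tip filtering is applied before the BFS, so a junction whose extra
branches are all short dead ends is walked straight through.

Emitted contigs shorter than 100 bp (configurable) are discarded; the
output sequence is the lexicographically smaller of the contig and its
reverse complement, making output files byte-deterministic.

The choice through a BFS region is *consistent but arbitrary*: the
structure stores no abundances, so when a region is a genuine error
bubble (the same substitution present in ≥ d reads across a full
k-window run) the chosen path may embed the error branch, and that
contig is then not an exact substring of the source genome. At the
desk scale used in the tests (10 kb, 40×, 1% errors, d = 3) complete
error bubbles are rare (most error paths are tips), but they do occur
on some seeds; this is a property of the method, not of the
implementation.

A reference coverage implementation (`mark_all_nodes=True`) stores a
mark for *every* node, keyed by the canonical (k+1)-mer of each
traversed edge, and is consulted at exactly the same decision points.
The test suite asserts byte-identical assemblies between the two — the
operational form of the claim that storing complex nodes only loses
nothing.

## Synthetic data

The generator emulates the simplest shotgun experiment: an i.i.d.
uniform ACGT genome (optionally with planted exact repeats — unit
copied over non-overlapping positions), reads of fixed length at
uniform positions on both strands, i.i.d. substitution errors at a
per-base rate, everything derived from one seed. Defaults: 100 kb
genome, 100 bp reads, 40× coverage, 1% errors. The first two reads
are pinned to the genome ends so terminal k-mers are observable at
d = 1 (purely uniform starts leave ragged ends with coverage ~cov/L at
base 0, which would fail round trips for reasons unrelated to the
graph). Not modelled: indels, quality values, coverage biases,
chimeras — so passing tests say nothing about those failure modes on
real data.

The structure comparison builds, for each Bloom ratio r in a grid
(default 5..19 bits/k-mer), the exact structure and the Bloom-only
structure, assembles both with the identical traversal, and compares
against a plain hash-set-graph assembly. Assembly difference is exact
full-length substring matching (unmatched contig bases plus uncovered
reference bases) — a dependency-free stand-in for whole-genome
alignment that is adequate when differences are whole missing or
altered contigs. The exact structure's difference is zero at every
grid point; the Bloom-only difference grows as r shrinks. The length
filter is applied to both sides before comparison. The acceptance test
runs this at 20 kb (rather than the 100 kb default) to keep the suite
fast; the qualitative contrast is unchanged at larger scale.

## Numerical notes and degenerate inputs

* F* carries the reference-precision constant 2.08 (the exact optimum
  constant is 1.44/ln 2 ≈ 2.0775); tests that compare the closed form
  against grid minimisation allow the corresponding ~10⁻⁶ relative
  slack.
* The 0.6185 constant is the real-h optimum; integer-h filters land
  within ~10⁻³ of it.
* log-gamma self-information agrees with exact big-integer binomials
  to ~10⁻⁹ relative (asserted at k = 5).
* Empty read sets yield an empty solid list; the pipeline refuses to
  build a graph over an empty node set with a clear error.
* Odd k has no self-reverse-complement k-mers; even k is supported in
  the core (palindromes canonicalise to themselves) but odd k is the
  sensible choice for assembly, and all defaults use odd k.
* Isolated nodes assemble to single-k-mer contigs (discarded by the
  length filter); self-loops and hairpin re-entries are cut by the
  per-contig cycle guard.

## Limitations

Single-threaded, desk-scale Python: the point is the structure's
behavior (exactness, sizes in bits/k-mer, bounded working sets), not
wall-clock or absolute-memory parity with a C implementation. Memory
budgets bound working-set element counts; they are not enforced
process limits. k > 31, scaffolding, gap filling and paired-end
information are out of scope.
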