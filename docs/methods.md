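# Methods

## The measure

δ(S) = max_k d_k(S)/k, where d_k(S) counts distinct canonical k-mers
across all records of all inputs in S. Canonicalization (keep the
lexicographically smaller of a k-mer and its reverse complement under
A<C<G<T) makes δ strand-symmetric; keeping records separate means a
k-mer never spans a contig junction, so junction artifacts cannot
inflate d_k. Any window containing a non-ACGT symbol contributes
nothing — skipping is the established k-mer-counting convention and
avoids inventing sequence. δ is monotone under appending sequence and
is exactly 1 for a homopolymer; for non-degenerate input d_1 ≥ 1, so
δ ≥ 1 in exact mode.

## Finding k\*

d_k/k is treated as unimodal in k: it climbs while longer k-mers still
separate new contexts, and falls once d_k saturates. The sweep
evaluates d_k/k at a start k (default 14, a length at which most
genomic k-mers are already distinct), moves one step at a time toward
the larger neighboring ratio, and accepts the first k whose two
neighbors are both smaller — the three-point certificate. Boundary ks
(1, or the longest record length) waive the missing neighbor; ties
prefer the smaller k, which is deterministic and cheaper downstream.
The default start is clamped (with a warning) for inputs shorter than
14 bp; an explicitly requested start outside 1..max-record-length is an
error. First-local-maximum semantics are deliberate: no global check is
attempted, and the brute-force-oracle test quantifies how rarely the
profile is multimodal at test scale (the certificate still holds when
it is). Union sweeps start at the maximum of the component k\*s, which
is almost always within one step of the union's optimum.

Each k is evaluated at most once per sweep (memoized), and cardinality
memoization is keyed by the *set* of input digests, so the progressive
analysis — which revisits the same subsets across orderings — computes
each distinct union once.

## Exact backend

Canonical k-mers with k ≤ 32 are packed 2 bits/base into a uint64
(A=0, C=1, G=2, T=3 — integer order equals lexicographic order, so
min(code, rc-code) is the canonical form). Extraction is vectorized:
forward and reverse-complement codes are accumulated in k shift-or
passes over the whole record, and windows overlapping a non-ACGT base
are masked via a validity convolution. Members are kept as sorted
unique arrays; unions are `np.union1d`. k > 32 falls back to plain
string windows (only relevant for short inputs, where it is cheap).

## Sketch backend

A HyperLogLog sketch with m = 2^p registers; default p = 14 (16 KiB,
theoretical relative error ≈ 1.04/√m ≈ 0.8%), configurable 4..24.
Items are 2-bit-encoded canonical k-mers hashed by a seedable
splitmix64-finalizer avalanche hash (public-domain construction,
vectorized in numpy; k > 32 k-mers use keyed blake2b). The hash seed is
stored in the sketch so incompatible unions are detectable; sketches
are union-compatible iff p, k and hash seed all match.

Cardinality uses the Poisson-model maximum-likelihood estimator over
the register histogram: with rate λ = n/m per register,
P(K=0) = e^(−λ), P(K=j) = e^(−λ/2^j) − e^(−λ/2^(j−1)) for 1 ≤ j ≤ q
(q = 64−p), and P(K=q+1) = 1 − e^(−λ/2^q). The likelihood derivative
is written in terms of 1/expm1(λ/2^j) for numerical stability and
solved by bracketed Brent root-finding to relative tolerance 1e−9; the
all-zero sketch returns exactly 0. No small/large-range corrections are
layered on top — the MLE covers the full range. Estimates are left as
reals; δ ratios are never rounded.

## Growth analysis

Orderings are uniform random permutations drawn without replacement
(rejection sampling from a seeded PCG64 generator); when the requested
count reaches n!, all permutations are enumerated instead. The Heaps
fit uses the across-ordering mean δ curve, not per-ordering curves:
increments Δδ_i = mean δ_i − mean δ_{i−1} for i ≥ 2 (Δδ_1 is
undefined), fit by ordinary least squares on log Δδ versus log i —
deterministic and closed-form, unlike nonlinear fitting. α is reported
as the positive decay exponent, so the openness rule is directly
α ≤ 1 → open, α > 1 → closed. Non-positive increments (possible under
estimator noise) are dropped with a warning; fewer than two usable
points is an error.

## Similarity

J_k is computed by inclusion–exclusion from three cardinalities, which
works identically for both backends; in exact mode it equals the
set-intersection Jaccard by construction. KIJ substitutes δ for d_k.
In exact mode max(δA, δB) ≤ δ(A∪B) ≤ δA + δB guarantees KIJ ∈ [0, 1];
sketch noise can push values slightly outside, so they are clamped with
a warning naming the affected pair (downstream tree builders need
[0, 1]). The PHYLIP writer uses the square dialect with 10-character
labels and 6 decimals, the most widely parsed variant; the companion
TSV states this.

## Cache

Artifact identity is BLAKE2b-256 over the sorted component content
digests plus (k, mode, parameters), truncated to 32 hex characters for
portable filenames — the same inputs in any order give one key, so each
combination is built once even across processes sharing a directory.
Layout is `<root>/<mode>/k<k>/<key>.bin` with a JSON sidecar recording
component paths, digests and parameters. Writes are atomic (temp file +
rename): concurrent builders race safely and the last writer wins with
identical content. Editing a FASTA changes its digest and therefore the
key, so stale artifacts are simply never addressed again; `verify()`
additionally flags sidecars whose recorded path no longer matches its
recorded content.

## Synthetic data

The simulator emulates a clonal pangenome: one uniform-random base
genome and independently mutated copies (star phylogeny), with
substitutions (always to a different base), 1–10 bp indels, and one
novel random insert per copy. Defaults — 100 kb, 10 genomes, 1% SNPs,
5×10⁻⁴ indels/bp, ~500 bp novel insert — give per-copy divergence
typical of within-species haplotypes while staying exactly countable.
Per-genome RNG streams are split from one seed sequence, so extending a
spec never changes earlier genomes. A graded-divergence variant (copies
at increasing distance from a common ancestor) supports monotone-trend
checks on similarity.

What the simulator does *not* model: recombination, repeat expansion,
structural rearrangement beyond short indels, sequencing error, or
tree-structured relatedness beyond the graded variant. Passing tests
therefore demonstrate correctness of the measure and machinery on
clonal-like data with uniform base composition; they do not calibrate
expectations for real assemblies, whose repeat structure shifts k\*
upward and whose δ growth mixes novel sequence with artifact.

## Numerical and degenerate-input choices

- Cardinality ties in the sweep resolve to the smaller k.
- Inputs whose every window contains a non-ACGT base have no valid
  k-mers and raise an error rather than returning δ = 0.
- Sketch estimates are floats end-to-end; exact cardinalities are
  integers cast to float at the backend boundary.
- The estimator's bracket expansion caps at 2^70, far beyond any real
  register state; a fully saturated sketch would return inf.

## Problem sizes

The test suite and the reproduction script run on simulated pangenomes
of 5–10 genomes at 10–100 kb and estimator trials up to 10⁶ items —
sizes at which exact recounting remains a practical oracle for every
approximate path, which is the point of the design: every sketch-based
number in the package is cross-checked against an exact computation of
the same quantity.

## Known limitations

- First-local-maximum semantics are unverified against adversarial
  multimodal d_k/k profiles (documented, certificate-checked).
- Presence/absence only: multiset (abundance-weighted) variants of δ
  and KIJ are out of scope.
- 1−KIJ is a dissimilarity, not a proven metric; the triangle
  inequality is not asserted.
- The exact backend holds per-genome k-mer arrays in memory; it is an
  oracle-grade reference, not an out-of-core counter.
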