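# deltasketch

Measuring how much *distinct* sequence a growing genome collection
contains — and how much each new assembly adds — is surprisingly hard to
do in a way that doesn't depend on arbitrary parameter choices.
`deltasketch` implements a parameter-free answer built on the
substring-complexity measure δ from the string-compression literature,
for people studying pangenome growth and alignment-free genome
similarity.

For a collection *S* of DNA strings, let d<sub>k</sub>(S) be the number
of distinct *canonical* k-mers in *S* (a k-mer and its reverse
complement count once). Then

```
δ(S) = max_k  d_k(S) / k ,
```

with k\* denoting the maximizing k. Small k undercounts (few possible
k-mers); large k divides away the signal; the maximum sits at the point
of diminishing returns and needs no k chosen in advance. δ is found by
a three-point sweep over k (start k = 14 by default) that stops at the
first k with d<sub>k−1</sub>/(k−1) < d<sub>k</sub>/k > d<sub>k+1</sub>/(k+1).

Cardinalities come from either of two backends:

- **exact** — distinct canonical k-mer sets (2-bit packed, k ≤ 32 in
  one machine word);
- **approximate** — HyperLogLog sketches with a maximum-likelihood
  cardinality estimator. Sketch union is an elementwise register
  maximum and is *bit-identical* to sketching the pooled input, so δ of
  arbitrary genome unions is nearly free once per-genome sketches exist
  (they are cached on disk, content-addressed by a BLAKE2 checksum of
  the inputs).

On top of δ the package provides:

- **Pangenome growth** (`progressive`): δ of cumulative unions along
  random genome orderings; the mean per-step increments Δδ_i are fit
  with Heaps' law Δδ_i = K·i^(−α), calling the pangenome *open*
  (α ≤ 1, still accumulating novel sequence) or *closed* (α > 1).
- **k-independent Jaccard** (`kij`): KIJ(A,B) =
  (δ(A)+δ(B)−δ(A∪B)) / δ(A∪B), a Jaccard-style similarity with δ in
  place of d<sub>k</sub>, so no k must be picked; all-pairs 1−KIJ (and
  per-k 1−J<sub>k</sub>) distance matrices are written in PHYLIP and
  TSV form for downstream tree building.
- **A synthetic pangenome simulator** (`simdata`) — a base genome plus
  mutated copies — so everything is testable without downloads.

## Worked example

```python
from deltasketch import (PangenomeSimSpec, simulate_pangenome, ExactBackend,
                         SketchBackend, delta_value, progressive,
                         mean_delta_curve, fit_heaps, all_pairs)

genomes = simulate_pangenome(
    PangenomeSimSpec(base_length=100_000, n_genomes=10, seed=3))

r = delta_value(genomes, ExactBackend())
print(f"delta = {r.delta:.1f} at k* = {r.k_star}")

approx = delta_value(genomes, SketchBackend(p=14))
print(f"sketch estimate = {approx.delta:.1f} at k* = {approx.k_star}")

records = progressive(genomes, n_orderings=20, seed=42,
                      backend=ExactBackend())
print(fit_heaps(mean_delta_curve(records)).summary())
```

prints

```
delta = 17562.0 at k* = 11
sketch estimate = 17445.7 at k* = 12
Heaps-law fit on 9 steps (2..10):
  K     = 1438.51
  alpha = 0.264209
  call  = open (alpha <= 1)
```

The ten simulated haplotypes (100 kb, 1% SNP divergence) hold about
17.6 k units of substring complexity, best measured at 11-mers; the
16 KiB-per-genome sketches land within 0.7% of the exact value. Each
added haplotype contributes a roughly constant ~1.4 k of new
complexity (α ≈ 0.26 ≤ 1): with fresh point mutations in every copy,
this simulated pangenome is open.

The same analyses run from the shell:

```sh
deltasketch delta --exact genomes/*.fa          # δ, k*, d_k trace
deltasketch progressive --norder 120 --seed 42 --out growth genomes/*.fa
deltasketch kij --sketch-dir .sketches --out dist genomes/*.fa
deltasketch jaccard --k-range 2:59 --out jk genomes/*.fa
```

`--exact` switches any command to exact counting; `--sketch-dir`
enables the on-disk sketch cache, so repeated runs over the same
genomes rebuild nothing.

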