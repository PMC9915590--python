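"""The substring-complexity measure δ and its local-maximum sweep.

For a collection S of DNA strings, d_k(S) is the number of distinct
canonical k-mers in S and

    δ(S) = max_k d_k(S) / k.

The maximizing k is written k*. As a function of k, d_k/k typically
rises while new k-mers keep appearing and falls once k-mers stop being
gained, so the maximum is found by a sweep: evaluate d_k/k at a starting
k (default 14) and walk toward the larger neighbor until three
consecutive values satisfy

    d_{k-1}/(k-1)  <  d_k/k  >  d_{k+1}/(k+1).

The first k meeting this local-maximum certificate is accepted; at the
domain boundary (k = 1, or k = longest record length) the missing
neighbor condition is waived. When unioning inputs whose k*s are already
known, the sweep starts at the maximum of the component k*s.

Cardinalities come from either backend: exact (distinct-k-mer sets) or
approximate (HyperLogLog sketches, which make unions cheap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from . import hll, kmers
from .io_fasta import GenomeInput

__all__ = [
    "DEFAULT_START_K",
    "DeltaResult",
    "CardinalityBackend",
    "ExactBackend",
    "SketchBackend",
    "delta_value",
    "delta_union",
]

DEFAULT_START_K = 14


@dataclass(frozen=True)
class DeltaResult:
    """δ of one input set: the value, the argmax k*, and the sweep trace."""

    delta: float
    k_star: int
    trace: dict[int, float]  # every evaluated k -> its cardinality d_k
    mode: str  # "exact" | "approximate"
    source_digests: tuple[str, ...] = ()

    def report(self) -> str:
        """Key-value text report of the result."""
        lines = [
            f"mode\t{self.mode}",
            f"delta\t{self.delta!r}",
            f"k_star\t{self.k_star}",
        ]
        for k in sorted(self.trace):
            lines.append(f"d_{k}\t{self.trace[k]!r}")
        for d in self.source_digests:
            lines.append(f"input_digest\t{d}")
        return "\n".join(lines) + "\n"


class CardinalityBackend(Protocol):
    """Pure, memoized map from (input set, k) to cardinality d_k."""

    mode: str

    def cardinality(self, genomes: Sequence[GenomeInput], k: int) -> float: ...


def _digests(genomes: Sequence[GenomeInput]) -> tuple[str, ...]:
    return tuple(sorted({g.digest for g in genomes}))


class ExactBackend:
    """Exact d_k via distinct canonical k-mer sets.

    Per-genome member arrays are cached per (genome, k); union
    cardinalities are memoized per (input set, k) so that repeated
    sweeps over overlapping subsets (as in the progressive analysis)
    never rescan sequence.
    """

    mode = "exact"

    def __init__(self, store=None):
        self._sets: dict[tuple[str, int], kmers.CanonicalKmerSet] = {}
        self._cards: dict[tuple[tuple[str, ...], int], float] = {}
        self.store = store

    def kmer_set(self, genome: GenomeInput, k: int) -> kmers.CanonicalKmerSet:
        key = (genome.digest, k)
        if key not in self._sets:
            if self.store is not None:
                self._sets[key] = self.store.get_or_build_exact([genome], k)
            else:
                self._sets[key] = kmers.count_distinct([genome], k)
        return self._sets[key]

    def cardinality(self, genomes: Sequence[GenomeInput], k: int) -> float:
        key = (_digests(genomes), k)
        if key not in self._cards:
            parts = [self.kmer_set(g, k) for g in genomes]
            merged = parts[0]
            for part in parts[1:]:
                merged = kmers.union_exact(merged, part)
            self._cards[key] = float(merged.cardinality)
        return self._cards[key]


class SketchBackend:
    """Approximate d_k via HyperLogLog sketches.

    Component sketches are built once per (genome, k); union sketches
    are register maxima of cached components, so no FASTA is re-read
    once its per-k sketch exists. An optional content-addressed store
    persists component sketches across processes.
    """

    mode = "approximate"

    def __init__(self, p: int = hll.DEFAULT_P,
                 hash_seed: int = hll.DEFAULT_HASH_SEED, store=None):
        self.p = p
        self.hash_seed = hash_seed
        self.store = store
        self._sketches: dict[tuple[str, int], hll.HllSketch] = {}
        self._cards: dict[tuple[tuple[str, ...], int], float] = {}

    @property
    def params(self) -> tuple[int, int]:
        return (self.p, self.hash_seed)

    def sketch(self, genome: GenomeInput, k: int) -> hll.HllSketch:
        key = (genome.digest, k)
        if key not in self._sketches:
            if self.store is not None:
                self._sketches[key] = self.store.get_or_build_sketch(
                    [genome], k, p=self.p, hash_seed=self.hash_seed
                )
            else:
                self._sketches[key] = hll.sketch_genomes(
                    [genome], k, p=self.p, hash_seed=self.hash_seed
                )
        return self._sketches[key]

    def union_sketch(self, genomes: Sequence[GenomeInput], k: int) -> hll.HllSketch:
        merged = self.sketch(genomes[0], k)
        for g in genomes[1:]:
            merged = hll.union_sketch(merged, self.sketch(g, k))
        return merged

    def cardinality(self, genomes: Sequence[GenomeInput], k: int) -> float:
        key = (_digests(genomes), k)
        if key not in self._cards:
            self._cards[key] = hll.estimate_cardinality(
                self.union_sketch(genomes, k)
            )
        return self._cards[key]


def _sweep(evaluate, start_k: int, k_min: int, k_max: int) -> tuple[int, dict[int, float]]:
    """Walk from start_k toward increasing d_k/k until the three-point
    local-maximum certificate holds. Ties prefer the smaller k."""
    trace: dict[int, float] = {}

    def ratio(k: int) -> float:
        if k not in trace:
            trace[k] = evaluate(k)
        return trace[k] / k

    k = start_k
    while True:
        here = ratio(k)
        right = ratio(k + 1) if k + 1 <= k_max else -np.inf
        left = ratio(k - 1) if k - 1 >= k_min else -np.inf
        if right > here and right >= left:
            k += 1
        elif left > here:
            k -= 1
        else:
            return k, trace


def delta_value(
    genomes: Sequence[GenomeInput],
    backend: CardinalityBackend,
    start_k: Optional[int] = None,
) -> DeltaResult:
    """Compute δ of the pooled genomes with the local-maximum sweep.

    ``start_k=None`` uses the default (14), clamped into the valid k
    range with a warning when the inputs are shorter; an explicit
    ``start_k`` outside the range is an error.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    k_max = max(g.max_record_length for g in genomes)
    if start_k is None:
        start = DEFAULT_START_K
        if start > k_max:
            warnings.warn(
                f"default start k={DEFAULT_START_K} exceeds the longest "
                f"record ({k_max} bp); clamping to {k_max}"
            )
            start = k_max
    else:
        if not 1 <= start_k <= k_max:
            raise ValueError(
                f"start_k={start_k} outside valid range 1..{k_max}"
            )
        start = start_k
    k_star, trace = _sweep(
        lambda k: backend.cardinality(genomes, k), start, 1, k_max
    )
    if trace[k_star] == 0:
        raise ValueError("inputs contain no valid (ACGT) k-mers")
    return DeltaResult(
        delta=trace[k_star] / k_star,
        k_star=k_star,
        trace=trace,
        mode=backend.mode,
        source_digests=_digests(genomes),
    )


def delta_union(
    parts: Sequence[tuple[Sequence[GenomeInput], DeltaResult]],
    backend: CardinalityBackend,
) -> DeltaResult:
    """δ of the union of already-measured input sets.

    The sweep starts at the maximum of the components' k*s. In
    approximate mode the per-k union sketches are register maxima of the
    backend's cached component sketches.
    """
    if not parts:
        raise ValueError("need at least one component")
    pooled: list[GenomeInput] = []
    seen: set[str] = set()
    for genomes, _result in parts:
        for g in genomes:
            if g.digest not in seen:
                seen.add(g.digest)
                pooled.append(g)
    start = max(result.k_star for _genomes, result in parts)
    k_max = max(g.max_record_length for g in pooled)
    return delta_value(pooled, backend, start_k=min(start, k_max))
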