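"""Pangenome growth: progressive δ over random genome orderings and the
Heaps-law openness fit.

The progressive analysis draws random orderings (permutations) of the
input genomes and, for each ordering, computes δ of the cumulative union
after each added genome. Averaging the step-i values across orderings
estimates δ over all size-i subsets. The per-step increments of that
mean curve,

    Δδ_i = mean δ_i − mean δ_{i-1}   (i >= 2),

are fit with a Heaps-law power decay Δδ_i = K · i^(−α) by least squares
on log Δδ versus log i. The pangenome is called *open* (still gaining
novel sequence) when α <= 1 and *closed* when α > 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, TextIO

import numpy as np

from .delta import CardinalityBackend, DeltaResult, delta_union, delta_value
from .io_fasta import GenomeInput

__all__ = [
    "GrowthRecord",
    "HeapsFit",
    "sample_orderings",
    "progressive",
    "mean_delta_curve",
    "fit_heaps",
    "write_progressive_tsv",
]


@dataclass(frozen=True)
class GrowthRecord:
    """δ of the first ``step`` genomes of one ordering."""

    ordering_id: int
    step: int
    genome_label: str
    genome_digest: str
    delta: float
    k_star: int


@dataclass(frozen=True)
class HeapsFit:
    """Heaps-law fit Δδ_i = K·i^(−α) with the openness call."""

    K: float
    alpha: float
    openness: str  # "open" (alpha <= 1) | "closed" (alpha > 1)
    fit_range: tuple[int, ...]  # steps whose Δδ entered the fit

    def summary(self) -> str:
        return (
            f"Heaps-law fit on {len(self.fit_range)} steps "
            f"({self.fit_range[0]}..{self.fit_range[-1]}):\n"
            f"  K     = {self.K:.6g}\n"
            f"  alpha = {self.alpha:.6g}\n"
            f"  call  = {self.openness} "
            f"({'alpha <= 1' if self.openness == 'open' else 'alpha > 1'})\n"
        )


def sample_orderings(
    n_genomes: int, n_orderings: int, seed: int
) -> list[tuple[int, ...]]:
    """Distinct random permutations of range(n_genomes), drawn uniformly
    without replacement; all n! permutations when n_orderings >= n!."""
    if n_genomes < 1 or n_orderings < 1:
        raise ValueError("n_genomes and n_orderings must be >= 1")
    total: Optional[int] = None
    if n_genomes <= 20:  # 20! > 2*10^18; beyond that n_orderings < n! always
        total = math.factorial(n_genomes)
    if total is not None and n_orderings >= total:
        import itertools

        return list(itertools.permutations(range(n_genomes)))
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(chosen) < n_orderings:
        perm = tuple(int(x) for x in rng.permutation(n_genomes))
        if perm not in seen:
            seen.add(perm)
            chosen.append(perm)
    return chosen


def progressive(
    genomes: Sequence[GenomeInput],
    n_orderings: int,
    seed: int,
    backend: CardinalityBackend,
    labels: Optional[Sequence[str]] = None,
) -> list[GrowthRecord]:
    """δ of every cumulative union along every sampled ordering.

    Component genomes are preprocessed once (their δ and k* feed the
    union sweeps as starting points); identical prefix sets occurring in
    different orderings are computed once via the backend's memoization.
    """
    if len(genomes) < 2:
        raise ValueError("progressive analysis needs at least 2 genomes")
    if labels is None:
        labels = [g.label or f"g{i}" for i, g in enumerate(genomes)]
    if len(labels) != len(genomes):
        raise ValueError("labels must match genomes")

    singles: list[DeltaResult] = [delta_value([g], backend) for g in genomes]
    orderings = sample_orderings(len(genomes), n_orderings, seed)

    union_cache: dict[frozenset[str], DeltaResult] = {}
    records: list[GrowthRecord] = []
    for oid, perm in enumerate(orderings):
        for step in range(1, len(perm) + 1):
            idxs = perm[:step]
            key = frozenset(genomes[i].digest for i in idxs)
            if key not in union_cache:
                if step == 1:
                    union_cache[key] = singles[idxs[0]]
                else:
                    parts = [([genomes[i]], singles[i]) for i in idxs]
                    union_cache[key] = delta_union(parts, backend)
            res = union_cache[key]
            added = perm[step - 1]
            records.append(
                GrowthRecord(
                    ordering_id=oid,
                    step=step,
                    genome_label=labels[added],
                    genome_digest=genomes[added].digest,
                    delta=res.delta,
                    k_star=res.k_star,
                )
            )
    return records


def mean_delta_curve(records: Sequence[GrowthRecord]) -> list[tuple[int, float]]:
    """Across-ordering mean δ at each step."""
    by_step: dict[int, list[float]] = {}
    for rec in records:
        by_step.setdefault(rec.step, []).append(rec.delta)
    return [(step, float(np.mean(vals))) for step, vals in sorted(by_step.items())]


def fit_heaps(mean_deltas: Sequence[tuple[int, float]]) -> HeapsFit:
    """Fit Δδ_i = K·i^(−α) to the increments of a mean-δ curve.

    Non-positive increments (possible under estimator noise) are dropped
    with a warning; at least two usable points are required.
    """
    if len(mean_deltas) < 3:
        raise ValueError("need at least 3 steps to fit growth increments")
    pts = sorted(mean_deltas)
    steps = []
    increments = []
    for (_, prev), (i, cur) in zip(pts, pts[1:]):
        d = cur - prev
        if d <= 0:
            warnings.warn(f"non-positive Δδ at step {i}; dropped from fit")
            continue
        steps.append(i)
        increments.append(d)
    if len(steps) < 2:
        raise ValueError("fewer than 2 usable (positive) Δδ points")
    x = np.log(np.asarray(steps, dtype=float))
    y = np.log(np.asarray(increments, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    alpha = -float(slope)
    K = float(np.exp(intercept))
    openness = "open" if alpha <= 1 else "closed"
    return HeapsFit(K=K, alpha=alpha, openness=openness,
                    fit_range=tuple(steps))


def write_progressive_tsv(
    records: Sequence[GrowthRecord],
    out: TextIO | str | Path,
    header_meta: Optional[dict] = None,
) -> None:
    """TSV of per-ordering per-step records, with config echoed in '#'
    header lines for reproducibility."""
    own = isinstance(out, (str, Path))
    fh: TextIO = open(out, "w") if own else out  # type: ignore[assignment]
    try:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("ordering_id\tstep\tgenome_label\tgenome_digest\tdelta\tk_star\n")
        for rec in records:
            fh.write(
                f"{rec.ordering_id}\t{rec.step}\t{rec.genome_label}\t"
                f"{rec.genome_digest}\t{rec.delta!r}\t{rec.k_star}\n"
            )
    finally:
        if own:
            fh.close()
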