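"""Alignment-free similarity: k-specific Jaccard and k-independent Jaccard.

The Jaccard coefficient over canonical k-mer sets can be computed from
three cardinalities by inclusion–exclusion,

    J_k(A,B) = (d_k(A) + d_k(B) − d_k(A∪B)) / d_k(A∪B),

which needs only the per-set and union cardinalities — exactly what the
sketch backend provides. Replacing d_k with δ removes the choice of k
entirely, giving the k-independent Jaccard:

    KIJ(A,B) = (δ(A) + δ(B) − δ(A∪B)) / δ(A∪B).

In exact mode both quantities are provably in [0,1]; the approximate
backend can stray slightly outside from estimator noise, in which case
values are clamped with a warning. Distances (1 − similarity) are
emitted as labeled symmetric matrices with PHYLIP and TSV writers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, TextIO

import numpy as np

from .delta import CardinalityBackend, DeltaResult, delta_union, delta_value
from .io_fasta import GenomeInput

__all__ = [
    "DistanceMatrix",
    "kij",
    "jaccard_k",
    "all_pairs",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str  # "one_minus_kij" | "one_minus_jk(k)"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("entries must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def write_phylip(self, out: TextIO | str | Path) -> None:
        """Square-dialect PHYLIP: labels padded/truncated to 10 chars,
        6 decimal places."""
        own = isinstance(out, (str, Path))
        fh: TextIO = open(out, "w") if own else out  # type: ignore[assignment]
        try:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                name = f"{label[:10]:<10}"
                fh.write(name + " ".join(f"{v:.6f}" for v in row) + "\n")
        finally:
            if own:
                fh.close()

    def write_tsv(self, out: TextIO | str | Path) -> None:
        """Long-format TSV: label_a, label_b, metric, value (PHYLIP
        companion; notes the square dialect)."""
        own = isinstance(out, (str, Path))
        fh: TextIO = open(out, "w") if own else out  # type: ignore[assignment]
        try:
            fh.write("# companion to the square-dialect PHYLIP matrix\n")
            fh.write("label_a\tlabel_b\tmetric\tvalue\n")
            for i, a in enumerate(self.labels):
                for j, b in enumerate(self.labels):
                    if j <= i:
                        continue
                    fh.write(f"{a}\t{b}\t{self.metric}\t{self.values[i, j]!r}\n")
        finally:
            if own:
                fh.close()


def kij(
    a_result: DeltaResult,
    b_result: DeltaResult,
    union_result: DeltaResult,
    clamp: bool = True,
) -> float:
    """k-independent Jaccard from three δ results (same backend/params)."""
    if union_result.delta == 0:
        raise ValueError("δ of the union is zero; inputs must be non-empty")
    value = (a_result.delta + b_result.delta - union_result.delta) / union_result.delta
    if clamp and not 0.0 <= value <= 1.0:
        warnings.warn(
            f"KIJ={value!r} outside [0,1] (estimator noise); clamped"
        )
        value = min(1.0, max(0.0, value))
    return value


def jaccard_k(
    genomes_a: Sequence[GenomeInput],
    genomes_b: Sequence[GenomeInput],
    k: int,
    backend: CardinalityBackend,
    clamp: bool = True,
) -> float:
    """J_k by inclusion–exclusion over backend cardinalities."""
    if k < 1:
        raise ValueError("k must be >= 1")
    da = backend.cardinality(genomes_a, k)
    db = backend.cardinality(genomes_b, k)
    pooled: list[GenomeInput] = list(genomes_a)
    seen = {g.digest for g in genomes_a}
    pooled.extend(g for g in genomes_b if g.digest not in seen)
    dab = backend.cardinality(pooled, k)
    if dab == 0:
        raise ValueError("empty union: no valid k-mers at this k")
    value = (da + db - dab) / dab
    if clamp and not 0.0 <= value <= 1.0:
        warnings.warn(f"J_{k}={value!r} outside [0,1] (estimator noise); clamped")
        value = min(1.0, max(0.0, value))
    return value


def all_pairs(
    inputs: Sequence[tuple[str, GenomeInput]],
    backend: CardinalityBackend,
    metric: str = "one_minus_kij",
    k: Optional[int] = None,
) -> DistanceMatrix:
    """All-pairwise 1−KIJ (or 1−J_k) distance matrix.

    ``inputs`` are (label, genome) pairs with unique labels; labels are
    sorted internally so the matrix does not depend on input order.
    Each pairwise union is evaluated exactly once, and every union sweep
    starts at the larger of the two singleton k*s.
    """
    if len(inputs) < 2:
        raise ValueError("need at least 2 inputs")
    labels = [lab for lab, _ in inputs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    ordered = sorted(inputs, key=lambda t: t[0])
    labels = tuple(lab for lab, _ in ordered)
    genomes = [g for _, g in ordered]
    n = len(genomes)
    values = np.zeros((n, n))

    if metric == "one_minus_kij":
        singles = [delta_value([g], backend) for g in genomes]
        for i in range(n):
            for j in range(i + 1, n):
                union = delta_union(
                    [([genomes[i]], singles[i]), ([genomes[j]], singles[j])],
                    backend,
                )
                sim = kij(singles[i], singles[j], union)
                values[i, j] = values[j, i] = 1.0 - sim
        metric_name = "one_minus_kij"
    elif metric == "one_minus_jk":
        if k is None:
            raise ValueError("metric one_minus_jk requires k")
        for i in range(n):
            for j in range(i + 1, n):
                sim = jaccard_k([genomes[i]], [genomes[j]], k, backend)
                values[i, j] = values[j, i] = 1.0 - sim
        metric_name = f"one_minus_jk({k})"
    else:
        raise ValueError(f"unknown metric {metric!r}")

    return DistanceMatrix(labels=labels, values=values, metric=metric_name)
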