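"""Approximate cardinality backend: HyperLogLog sketches of canonical k-mers.

A sketch is an array of m = 2**p small registers. Each item is hashed to
64 bits; the top p bits pick a register and the position of the first
1-bit in the remainder (the "rank") updates that register by maximum.
Sketch union is the elementwise register maximum and is bit-identical to
sketching the pooled input, which is what makes pangenome unions cheap.

Cardinality is recovered with the Poisson-model maximum-likelihood
estimator (Ertl): register i sees a Poisson(n/m) number of distinct
items, giving register-value probabilities

    P(K=0) = exp(-lam),
    P(K=j) = exp(-lam/2^j) - exp(-lam/2^(j-1)),   1 <= j <= q,
    P(K=q+1) = 1 - exp(-lam/2^q),

with q = 64 - p and lam = n/m; the log-likelihood over the register
histogram is maximized in lam by a bracketed 1-D root find on its
derivative.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .io_fasta import GenomeInput
from .kmers import MAX_PACKED_K, _canonical_strings, canonical_codes

__all__ = [
    "HllSketch",
    "sketch_genomes",
    "union_sketch",
    "estimate_cardinality",
    "hash64",
]

DEFAULT_P = 14
DEFAULT_HASH_SEED = 0

_U = np.uint64
_MAGIC = b"DSKHLL01"


def hash64(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seedable 64-bit avalanche hash (splitmix64 finalizer) of uint64s."""
    with np.errstate(over="ignore"):  # mod-2^64 wraparound is the point
        z = np.asarray(values, dtype=np.uint64) ^ _mix_scalar(np.uint64(seed))
        z = z + _U(0x9E3779B97F4A7C15)
        z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
        return z ^ (z >> _U(31))


def _mix_scalar(x: np.uint64) -> np.uint64:
    with np.errstate(over="ignore"):
        z = x + _U(0x9E3779B97F4A7C15)
        z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
        return z ^ (z >> _U(31))


def _hash_bytes(data: bytes, seed: int) -> int:
    key = int(seed).to_bytes(8, "little", signed=False)
    return int.from_bytes(
        hashlib.blake2b(data, digest_size=8, key=key).digest(), "little"
    )


@dataclass
class HllSketch:
    """HyperLogLog sketch over canonical k-mers.

    Two sketches are union-compatible iff ``p``, ``k`` and ``hash_seed``
    all match; ``source_digests`` records which genomes contributed.
    """

    p: int
    k: int
    hash_seed: int
    registers: np.ndarray  # uint8, length 2**p, values in [0, 64)
    source_digests: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 4 <= self.p <= 24:
            raise ValueError(f"p={self.p} outside supported range 4..24")
        self.registers = np.asarray(self.registers, dtype=np.uint8)
        if self.registers.shape != (1 << self.p,):
            raise ValueError("register array length must be 2**p")

    @classmethod
    def empty(
        cls, p: int = DEFAULT_P, k: int = 0, hash_seed: int = DEFAULT_HASH_SEED
    ) -> "HllSketch":
        return cls(p=p, k=k, hash_seed=hash_seed,
                   registers=np.zeros(1 << p, dtype=np.uint8))

    @property
    def m(self) -> int:
        return 1 << self.p

    def update_hashes(self, hashes: np.ndarray) -> None:
        """Insert pre-hashed 64-bit values."""
        h = np.asarray(hashes, dtype=np.uint64)
        if h.size == 0:
            return
        q = 64 - self.p
        idx = (h >> _U(q)).astype(np.intp)
        w = h & ((_U(1) << _U(q)) - _U(1))
        # rank = leading zeros of the q-bit remainder, plus 1
        nbits = np.zeros(h.shape, dtype=np.uint8)
        wv = w.copy()
        for shift in (32, 16, 8, 4, 2, 1):
            mask = wv >> _U(shift) != 0
            nbits[mask] += shift
            wv[mask] >>= _U(shift)
        nbits[wv != 0] += 1  # bit_length
        rank = (q - nbits.astype(np.int32)) + 1
        np.maximum.at(self.registers, idx, rank.astype(np.uint8))

    def update_codes(self, codes: np.ndarray) -> None:
        """Hash and insert packed k-mer codes (or any uint64 items)."""
        self.update_hashes(hash64(codes, seed=self.hash_seed))

    def update_strings(self, kmers: Sequence[str]) -> None:
        hashes = np.fromiter(
            (_hash_bytes(s.encode(), self.hash_seed) for s in kmers),
            dtype=np.uint64,
            count=len(kmers),
        )
        self.update_hashes(hashes)

    def copy(self) -> "HllSketch":
        return HllSketch(p=self.p, k=self.k, hash_seed=self.hash_seed,
                         registers=self.registers.copy(),
                         source_digests=self.source_digests)

    # -- serialization: magic, version, p, k, hash_seed, digests, registers
    def dumps(self) -> bytes:
        digests = "\n".join(self.source_digests).encode()
        head = struct.pack(
            "<8sBBIQI", _MAGIC, 1, self.p, self.k, self.hash_seed, len(digests)
        )
        return head + digests + self.registers.tobytes()

    @classmethod
    def loads(cls, data: bytes) -> "HllSketch":
        head_size = struct.calcsize("<8sBBIQI")
        magic, version, p, k, hash_seed, dlen = struct.unpack(
            "<8sBBIQI", data[:head_size]
        )
        if magic != _MAGIC or version != 1:
            raise ValueError("not a sketch file (bad magic/version)")
        blob = data[head_size : head_size + dlen].decode()
        digests = tuple(blob.split("\n")) if blob else ()
        registers = np.frombuffer(
            data[head_size + dlen :], dtype=np.uint8
        ).copy()
        return cls(p=p, k=k, hash_seed=hash_seed, registers=registers,
                   source_digests=digests)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(self.dumps())

    @classmethod
    def load(cls, path: str | Path) -> "HllSketch":
        return cls.loads(Path(path).read_bytes())


def sketch_genomes(
    genomes: Sequence[GenomeInput],
    k: int,
    p: int = DEFAULT_P,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> HllSketch:
    """Sketch every canonical k-mer of the given genomes.

    Extraction follows the exact backend's contract: canonical form,
    non-ACGT windows skipped, no k-mers across record boundaries. An
    empty genome list yields the all-zero sketch.
    """
    sketch = HllSketch.empty(p=p, k=k, hash_seed=hash_seed)
    for genome in genomes:
        for rec in genome.records:
            if k <= MAX_PACKED_K:
                sketch.update_codes(canonical_codes(rec.seq, k))
            else:
                sketch.update_strings(_canonical_strings(rec.seq, k))
    sketch.source_digests = tuple(sorted({g.digest for g in genomes}))
    return sketch


def union_sketch(a: HllSketch, b: HllSketch) -> HllSketch:
    """Elementwise-maximum union; bit-identical to sketching A ∪ B."""
    for attr in ("p", "k", "hash_seed"):
        if getattr(a, attr) != getattr(b, attr):
            raise ValueError(
                f"sketches are not union-compatible: {attr} differs "
                f"({getattr(a, attr)} vs {getattr(b, attr)})"
            )
    return HllSketch(
        p=a.p, k=a.k, hash_seed=a.hash_seed,
        registers=np.maximum(a.registers, b.registers),
        source_digests=tuple(sorted(set(a.source_digests) | set(b.source_digests))),
    )


def _loglik_derivative(lam: float, counts: np.ndarray, q: int) -> float:
    # d/dlam of the Poisson-model log-likelihood; see module docstring.
    val = -float(counts[0])
    js = np.nonzero(counts[1 : q + 1])[0] + 1
    if js.size:
        cj = counts[js].astype(float)
        pow2 = np.exp2(-js.astype(float))  # 1/2^j
        with np.errstate(over="ignore"):
            inv = 1.0 / np.expm1(lam * pow2)
        val += float(np.sum(cj * pow2 * (inv - 1.0)))
    if counts[q + 1]:
        pq = 2.0 ** (-q)
        with np.errstate(over="ignore"):
            val += float(counts[q + 1]) * pq / np.expm1(lam * pq)
    return val


def estimate_cardinality(sketch: HllSketch) -> float:
    """Maximum-likelihood cardinality estimate from the register histogram.

    The all-zero sketch estimates exactly 0. A fully saturated sketch
    (every register at its ceiling) has an unbounded likelihood and
    returns ``inf``; this cannot occur for realistic inputs at p >= 4.
    """
    q = 64 - sketch.p
    counts = np.bincount(sketch.registers, minlength=q + 2)
    m = sketch.m
    if counts[0] == m:
        return 0.0
    if counts[: q + 1].sum() == 0:
        return float("inf")

    def f(lam: float) -> float:
        return _loglik_derivative(lam, counts, q)

    # f decreases from +inf at 0+; expand until the bracket straddles the root
    hi = 1.0
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 2.0**70:  # unreachable for valid sketches
            return float("inf")
    lo = max(hi / 2.0**30, 1e-12)
    while f(lo) < 0.0:
        lo /= 2.0
    lam = brentq(f, lo, hi, rtol=1e-9, xtol=1e-300)
    return m * lam
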