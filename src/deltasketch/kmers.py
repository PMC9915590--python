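"""Canonical k-mer extraction and the exact cardinality backend.

A DNA k-mer and its reverse complement are treated as one object by
keeping only the *canonical* form — the lexicographically smaller of the
two under A<C<G<T. For k <= 32 canonical k-mers are packed into 2-bit
codes in a single 64-bit word (A=0, C=1, G=2, T=3, so integer order
equals lexicographic order); longer k-mers fall back to strings.

Windows containing any non-ACGT symbol are skipped, and k-mers never
span record (contig) boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .io_fasta import GenomeInput

__all__ = [
    "canonicalize",
    "revcomp",
    "canonical_codes",
    "count_distinct",
    "union_exact",
    "CanonicalKmerSet",
    "MAX_PACKED_K",
]

MAX_PACKED_K = 32  # 2 bits/base in one uint64

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; anything non-ACGT maps to -1
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the lexicographically smaller of ``kmer`` and its reverse
    complement (A<C<G<T). Idempotent. Raises on non-ACGT symbols."""
    if not kmer:
        raise ValueError("k-mer must be non-empty")
    if any(c not in "ACGT" for c in kmer):
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def canonical_codes(seq: str, k: int) -> np.ndarray:
    """All canonical k-mer codes (with duplicates) of one sequence, k <= 32.

    Returns a uint64 array, one entry per valid window in left-to-right
    order; windows containing a non-ACGT base are dropped.
    """
    if not 1 <= k <= MAX_PACKED_K:
        raise ValueError(f"k={k} outside packed range 1..{MAX_PACKED_K}")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    invalid = codes < 0
    b = (codes & 3).astype(np.uint64)
    nwin = n - k + 1
    fwd = np.zeros(nwin, dtype=np.uint64)
    rev = np.zeros(nwin, dtype=np.uint64)
    for j in range(k):
        window = b[j : j + nwin]
        fwd = (fwd << np.uint64(2)) | window
        rev |= (np.uint64(3) - window) << np.uint64(2 * j)
    if invalid.any():
        bad = np.convolve(invalid, np.ones(k, dtype=np.intp), mode="valid") > 0
        keep = ~bad
        fwd, rev = fwd[keep], rev[keep]
    return np.minimum(fwd, rev)


def _canonical_strings(seq: str, k: int) -> list[str]:
    # fallback path for k > 32: plain string windows
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(c not in "ACGT" for c in window):
            continue
        out.append(canonicalize(window))
    return out


Members = Union[np.ndarray, tuple[str, ...]]


@dataclass(frozen=True)
class CanonicalKmerSet:
    """The distinct canonical k-mers of an input collection at fixed k.

    ``members`` is a sorted, duplicate-free container: a uint64 code
    array for k <= 32, a tuple of strings otherwise. Cardinality is
    exact by construction.
    """

    k: int
    members: Members
    source_digests: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, kmer: str) -> bool:
        canon = canonicalize(kmer)
        if len(canon) != self.k:
            return False
        if isinstance(self.members, np.ndarray):
            code = encode_kmer(canon)
            idx = np.searchsorted(self.members, code)
            return bool(idx < len(self.members) and self.members[idx] == code)
        return canon in self.members

    def as_strings(self) -> list[str]:
        """Members decoded to sorted k-mer strings (debug/export)."""
        if isinstance(self.members, np.ndarray):
            return [decode_kmer(int(c), self.k) for c in self.members]
        return list(self.members)

    def write_text(self, path) -> None:
        """Export one canonical k-mer per line, sorted."""
        with open(path, "w") as out:
            for kmer in self.as_strings():
                out.write(kmer + "\n")


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string (len <= 32) into its 2-bit integer code."""
    code = 0
    for c in kmer:
        v = _CODE[ord(c)]
        if v < 0:
            raise ValueError(f"non-ACGT symbol in {kmer!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def count_distinct(genomes: Sequence[GenomeInput], k: int) -> CanonicalKmerSet:
    """Distinct canonical k-mers across every record of every genome."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not genomes:
        raise ValueError("need at least one genome")
    digests = tuple(sorted({g.digest for g in genomes}))
    if k <= MAX_PACKED_K:
        parts = [
            canonical_codes(rec.seq, k)
            for g in genomes
            for rec in g.records
        ]
        allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
        members: Members = np.unique(allcodes)
    else:
        strings: set[str] = set()
        for g in genomes:
            for rec in g.records:
                strings.update(_canonical_strings(rec.seq, k))
        members = tuple(sorted(strings))
    return CanonicalKmerSet(k=k, members=members, source_digests=digests)


def union_exact(a: CanonicalKmerSet, b: CanonicalKmerSet) -> CanonicalKmerSet:
    """Set union of two canonical k-mer sets (same k)."""
    if a.k != b.k:
        raise ValueError(f"cannot union k-mer sets with k={a.k} and k={b.k}")
    if isinstance(a.members, np.ndarray):
        members: Members = np.union1d(a.members, b.members)
    else:
        members = tuple(sorted(set(a.members) | set(b.members)))
    digests = tuple(sorted(set(a.source_digests) | set(b.source_digests)))
    return CanonicalKmerSet(k=a.k, members=members, source_digests=digests)
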