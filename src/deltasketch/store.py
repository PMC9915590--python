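"""Content-addressed, order-independent filesystem cache for sketches
and exact k-mer sets.

Building a sketch or k-mer set from FASTA is the expensive step;
unioning and estimating from existing artifacts is cheap. Artifacts are
therefore cached on disk under a key derived from a BLAKE2b checksum of
the *sorted* component genome digests plus (k, mode, parameters), so the
same combination of inputs — in any order — maps to one cache file and
is built exactly once. A JSON sidecar records provenance (component
paths, digests, parameters) so stale caches are detectable when a FASTA
changes underneath its recorded path.

Layout: ``<root>/<mode>/k<k>/<key>.bin`` plus ``<key>.meta.json``;
writes are atomic (temp file + rename), so concurrent builders race
safely — the last writer wins with identical content.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import hll, kmers
from .io_fasta import GenomeInput, read_fasta

__all__ = ["CacheKey", "SketchStore", "StaleCacheError"]


class StaleCacheError(RuntimeError):
    """Cached metadata disagrees with the FASTA content now on disk."""


@dataclass(frozen=True)
class CacheKey:
    """Identity of one cached artifact: inputs + k + backend parameters."""

    component_digests: tuple[str, ...]  # sorted
    k: int
    mode: str  # "exact" | "approximate"
    params: tuple[int, int] = ()  # (p, hash_seed) when approximate

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "component_digests", tuple(sorted(self.component_digests))
        )

    @property
    def key(self) -> str:
        h = hashlib.blake2b(digest_size=32)
        for d in self.component_digests:
            h.update(d.encode())
            h.update(b"\n")
        h.update(f"k={self.k};mode={self.mode};params={self.params}".encode())
        return h.hexdigest()[:32]  # truncated for portable filenames


class SketchStore:
    """Filesystem cache with get-or-build semantics."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.builds = 0  # builder invocations this process (log/testing)
        self.hits = 0

    def _paths(self, key: CacheKey) -> tuple[Path, Path]:
        d = self.root / key.mode / f"k{key.k}"
        return d / f"{key.key}.bin", d / f"{key.key}.meta.json"

    def get_or_build(
        self,
        key: CacheKey,
        builder: Callable[[], bytes],
        meta: Optional[dict] = None,
    ) -> Path:
        """Return the artifact path for ``key``, building it if absent.

        The builder runs at most once per missing key; persistence is
        atomic (write to a temp file, then rename).
        """
        artifact, sidecar = self._paths(key)
        if artifact.exists():
            self.hits += 1
            return artifact
        artifact.parent.mkdir(parents=True, exist_ok=True)
        data = builder()
        self.builds += 1
        for path, payload in (
            (artifact, data),
            (
                sidecar,
                json.dumps(
                    {
                        "key": key.key,
                        "component_digests": list(key.component_digests),
                        "k": key.k,
                        "mode": key.mode,
                        "params": list(key.params),
                        "created": time.time(),
                        **(meta or {}),
                    },
                    indent=1,
                ).encode(),
            ),
        ):
            fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
            with os.fdopen(fd, "wb") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        return artifact

    # -- typed wrappers -------------------------------------------------
    def get_or_build_sketch(
        self,
        genomes: Sequence[GenomeInput],
        k: int,
        p: int = hll.DEFAULT_P,
        hash_seed: int = hll.DEFAULT_HASH_SEED,
    ) -> hll.HllSketch:
        key = CacheKey(
            component_digests=tuple(g.digest for g in genomes),
            k=k,
            mode="approximate",
            params=(p, hash_seed),
        )
        path = self.get_or_build(
            key,
            lambda: hll.sketch_genomes(genomes, k, p=p, hash_seed=hash_seed).dumps(),
            meta={"paths": [str(g.path) for g in genomes if g.path]},
        )
        return hll.HllSketch.load(path)

    def get_or_build_exact(
        self, genomes: Sequence[GenomeInput], k: int
    ) -> kmers.CanonicalKmerSet:
        key = CacheKey(
            component_digests=tuple(g.digest for g in genomes),
            k=k,
            mode="exact",
        )

        def build() -> bytes:
            kset = kmers.count_distinct(genomes, k)
            if isinstance(kset.members, np.ndarray):
                body = kset.members.tobytes()
                kind = b"U8"
            else:
                body = "\n".join(kset.members).encode()
                kind = b"TX"
            head = "\n".join(kset.source_digests).encode()
            return kind + len(head).to_bytes(4, "little") + head + body

        path = self.get_or_build(
            key, build, meta={"paths": [str(g.path) for g in genomes if g.path]}
        )
        data = path.read_bytes()
        kind, hlen = data[:2], int.from_bytes(data[2:6], "little")
        digests = tuple(data[6 : 6 + hlen].decode().split("\n"))
        body = data[6 + hlen :]
        if kind == b"U8":
            members: kmers.Members = np.frombuffer(body, dtype=np.uint64).copy()
        else:
            members = tuple(body.decode().split("\n")) if body else ()
        return kmers.CanonicalKmerSet(k=k, members=members, source_digests=digests)

    def verify(self, key: CacheKey) -> None:
        """Check a cached artifact's recorded FASTA paths against their
        current content; raise :class:`StaleCacheError` on disagreement."""
        _artifact, sidecar = self._paths(key)
        if not sidecar.exists():
            return
        meta = json.loads(sidecar.read_text())
        recorded = set(meta["component_digests"])
        for p in meta.get("paths", []):
            path = Path(p)
            if not path.exists():
                continue
            digest = read_fasta(path).digest
            if digest not in recorded:
                raise StaleCacheError(
                    f"{path} no longer matches the content this cache entry "
                    f"was built from; delete the cache entry or rebuild"
                )
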