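"""Independent brute-force oracles used by the tests.

Deliberately naive, pure-Python, string-based implementations of
canonical k-mer counting and δ — kept separate from the package so they
can serve as a trusted cross-check of the optimized code paths.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def kmer_set(strings, k: int) -> set[str]:
    """Distinct canonical k-mers, skipping windows with non-ACGT bases;
    windows never span strings."""
    out: set[str] = set()
    for s in strings:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if all(c in "ACGT" for c in w):
                out.add(canon(w))
    return out


def d_k(strings, k: int) -> int:
    return len(kmer_set(strings, k))


def delta_profile(strings) -> dict[int, int]:
    kmax = max(len(s) for s in strings)
    return {k: d_k(strings, k) for k in range(1, kmax + 1)}


def brute_delta(strings) -> tuple[float, int]:
    """Global maximum of d_k/k over every k; ties go to the smaller k."""
    profile = delta_profile(strings)
    best_k = min(profile, key=lambda k: (-profile[k] / k, k))
    return profile[best_k] / best_k, best_k


def is_unimodal(ratios: list[float]) -> bool:
    """True when the sequence rises (weakly) then falls (weakly)."""
    diffs = [b - a for a, b in zip(ratios, ratios[1:])]
    seen_fall = False
    for d in diffs:
        if d < 0:
            seen_fall = True
        elif d > 0 and seen_fall:
            return False
    return True


def jaccard(strings_a, strings_b, k: int) -> float:
    sa, sb = kmer_set(strings_a, k), kmer_set(strings_b, k)
    return len(sa & sb) / len(sa | sb)
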