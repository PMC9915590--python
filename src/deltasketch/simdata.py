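"""Synthetic pangenome generator.

Emulates a clonal population: one uniform-random base genome plus
independently mutated copies (a star phylogeny). Each copy receives
point substitutions at ``snp_rate`` per base, short (1–10 bp) insertions
and deletions at ``indel_rate`` per base, and one novel insert of
never-before-seen random sequence with mean length ``novel_insert_bp``.
Because each copy shares most of its sequence with the base, δ of the
cumulative union grows sublinearly in the number of genomes — the
regime the growth analysis is designed to characterize.

Generation is fully deterministic: the random stream is split per
genome index (numpy SeedSequence spawning), so adding genomes to a spec
never perturbs the earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_fasta import GenomeInput, SequenceRecord, genome_from_records, write_fasta

__all__ = [
    "PangenomeSimSpec",
    "simulate_pangenome",
    "simulate_graded_divergence",
    "write_pangenome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PangenomeSimSpec:
    """Parameters of one synthetic clonal pangenome.

    Defaults model a 100-kb genome with ten haplotypes at 1% SNP
    divergence — small enough to recount exactly, large enough that
    sketch estimates concentrate.
    """

    base_length: int = 100_000
    n_genomes: int = 10
    snp_rate: float = 0.01
    indel_rate: float = 0.0005
    novel_insert_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_length < 1000:
            raise ValueError("base_length must be >= 1000")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for name in ("snp_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(
    base: np.ndarray,
    rng: np.random.Generator,
    snp_rate: float,
    indel_rate: float,
    novel_insert_bp: int,
) -> tuple[np.ndarray, dict[str, int]]:
    seq = base.copy()
    # substitutions: always to a different base
    snp_mask = rng.random(len(seq)) < snp_rate
    shifts = rng.integers(1, 4, size=int(snp_mask.sum()), dtype=np.uint8)
    seq[snp_mask] = (seq[snp_mask] + shifts) % 4
    n_snp = int(snp_mask.sum())

    # short indels, applied right-to-left so positions stay valid
    indel_pos = np.flatnonzero(rng.random(len(seq)) < indel_rate)
    n_ins = n_del = 0
    pieces = []
    prev = len(seq)
    for pos in indel_pos[::-1]:
        size = int(rng.integers(1, 11))
        if rng.random() < 0.5:  # deletion
            pieces.append(seq[min(pos + size, prev) : prev])
            n_del += 1
        else:  # insertion of random sequence
            pieces.append(seq[pos:prev])
            pieces.append(_random_seq(rng, size))
            n_ins += 1
        prev = pos
    pieces.append(seq[:prev])
    seq = np.concatenate(pieces[::-1]) if pieces else seq

    # one novel insert of never-before-seen sequence
    novel_len = int(rng.poisson(novel_insert_bp)) if novel_insert_bp > 0 else 0
    if novel_len > 0:
        at = int(rng.integers(0, len(seq) + 1))
        seq = np.concatenate([seq[:at], _random_seq(rng, novel_len), seq[at:]])
    return seq, {"snp": n_snp, "ins": n_ins, "del": n_del, "novel_bp": novel_len}


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_pangenome(
    spec: PangenomeSimSpec, out_dir: Optional[str | Path] = None
) -> list[GenomeInput]:
    """Generate the pangenome; optionally write FASTAs and a manifest TSV.

    Genome 0 is the random base; genomes 1..n−1 are independent mutated
    copies of it. Headers record the applied mutation counts.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_genomes)
    base = _random_seq(np.random.default_rng(children[0]), spec.base_length)

    genomes: list[GenomeInput] = []
    manifest: list[dict] = []
    for i in range(spec.n_genomes):
        if i == 0:
            seq = base
            stats = {"snp": 0, "ins": 0, "del": 0, "novel_bp": 0}
        else:
            seq, stats = _mutate(
                base,
                np.random.default_rng(children[i]),
                spec.snp_rate,
                spec.indel_rate,
                spec.novel_insert_bp,
            )
        label = f"g{i}"
        rec = SequenceRecord(id=label, seq=_to_str(seq))
        genome = genome_from_records([rec], label=label)
        genomes.append(genome)
        manifest.append({"label": label, **stats, "length": len(seq)})

    if out_dir is not None:
        genomes = write_pangenome(genomes, manifest, Path(out_dir), spec)
    return genomes


def write_pangenome(
    genomes: Sequence[GenomeInput],
    manifest: Sequence[dict],
    out_dir: Path,
    spec: PangenomeSimSpec,
) -> list[GenomeInput]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[GenomeInput] = []
    for genome in genomes:
        path = out_dir / f"{genome.label}.fa"
        write_fasta(genome.records, path)
        written.append(replace(genome, path=path))
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write(
            f"# base_length={spec.base_length} n_genomes={spec.n_genomes} "
            f"snp_rate={spec.snp_rate} indel_rate={spec.indel_rate} "
            f"novel_insert_bp={spec.novel_insert_bp} seed={spec.seed}\n"
        )
        fh.write("label\tfile\tlength\tsnp\tins\tdel\tnovel_bp\n")
        for row in manifest:
            fh.write(
                f"{row['label']}\t{row['label']}.fa\t{row['length']}\t"
                f"{row['snp']}\t{row['ins']}\t{row['del']}\t{row['novel_bp']}\n"
            )
    return written


def simulate_graded_divergence(
    base_length: int = 20_000,
    snp_rates: Sequence[float] = (0.002, 0.01, 0.02, 0.05, 0.1),
    seed: int = 0,
) -> list[GenomeInput]:
    """A base genome plus copies at increasing divergence from it.

    This is the split-lineage companion to :func:`simulate_pangenome`:
    copy i diverges from the common ancestor at ``snp_rates[i]``, so
    pairwise distance to the base should increase with rank — the
    monotone-trend fixture for similarity analyses.
    """
    children = np.random.SeedSequence(seed).spawn(len(snp_rates) + 1)
    base = _random_seq(np.random.default_rng(children[0]), base_length)
    genomes = [
        genome_from_records(
            [SequenceRecord(id="anc", seq=_to_str(base))], label="anc"
        )
    ]
    for i, rate in enumerate(snp_rates):
        seq, _ = _mutate(base, np.random.default_rng(children[i + 1]),
                         rate, 0.0, 0)
        label = f"div{i}"
        genomes.append(
            genome_from_records([SequenceRecord(id=label, seq=_to_str(seq))],
                                label=label)
        )
    return genomes
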