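"""Whole-genome shotgun read simulation (wgsim-like).

Generates single- or paired-end FASTQ reads from a genome at a requested
fold-coverage.  Fragments start uniformly along chromosomes chosen with
probability proportional to length; fragment lengths are
Normal(frag_mean, frag_sd) rounded and clamped; each base is substituted
independently with probability ``error_rate`` to a uniformly chosen
different base.  Qualities are a constant character.  The model is
substitution-only (no indels, no quality profile, no GC bias): it emulates
the sampling variance of real shotgun data, not platform artefacts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .formats_io import SequenceSet, reverse_complement

QUALITY_CHAR = "I"  # constant Phred quality for every base
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadSimParams:
    """Simulation parameters: read length, pairedness, fragment-size
    distribution, per-base substitution rate, fold-coverage, and seed."""

    read_len: int = 100
    paired: bool = True
    frag_mean: int = 300
    frag_sd: int = 50
    error_rate: float = 0.0
    fold_coverage: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.paired and self.frag_mean < self.read_len:
            raise ValueError("frag_mean must be >= read_len for paired reads")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.fold_coverage <= 0:
            raise ValueError("fold_coverage must be > 0")


@dataclass(frozen=True)
class FastqRead:
    """One FASTQ record with its recorded origin (chrom, fragment span)."""

    name: str
    seq: str
    chrom: str
    frag_start: int
    frag_len: int
    mate: int  # 1 or 2; 1 for single-end

    def fastq_lines(self) -> str:
        return f"@{self.name}\n{self.seq}\n+\n{QUALITY_CHAR * len(self.seq)}\n"


def n_fragments(genome_len: int, params: ReadSimParams) -> int:
    """Number of fragments needed to reach the requested fold-coverage.

    paired: round(cov * L / (2 * read_len)); single: round(cov * L / read_len).
    """
    if genome_len < params.read_len:
        raise ValueError(
            f"genome length {genome_len} shorter than read length {params.read_len}"
        )
    reads_per_fragment = 2 if params.paired else 1
    return int(
        round(
            params.fold_coverage * genome_len / (reads_per_fragment * params.read_len)
        )
    )


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    for i in hits:
        # uniformly choose a different base (N errors also become A/C/G/T)
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_reads(
    genome: SequenceSet, params: ReadSimParams
) -> Iterator[FastqRead]:
    """Simulate shotgun reads from ``genome``; deterministic given the seed.

    Fragments never span chromosome ends; out-of-range fragment lengths are
    clamped to [read_len, chrom length] rather than rejected, keeping the
    fragment count exact.  Read names encode chromosome, fragment start and
    a serial number (``frag<serial>|<chrom>|<start>``).
    """
    rng = np.random.default_rng(params.seed)
    names = genome.names()
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    if lengths.min() < params.read_len:
        raise ValueError("a chromosome is shorter than the read length")
    total = n_fragments(int(lengths.sum()), params)
    probs = lengths / lengths.sum()

    chrom_idx = rng.choice(len(names), size=total, p=probs)
    frag_lens = np.rint(rng.normal(params.frag_mean, params.frag_sd, size=total))
    starts_u = rng.random(total)

    for serial in range(total):
        chrom = names[chrom_idx[serial]]
        chrom_len = int(lengths[chrom_idx[serial]])
        frag_len = int(min(max(frag_lens[serial], params.read_len), chrom_len))
        start = int(starts_u[serial] * (chrom_len - frag_len + 1))
        fragment = genome[chrom][start : start + frag_len]
        base = f"frag{serial}|{chrom}|{start}"
        mate1 = _apply_errors(fragment[: params.read_len], rng, params.error_rate)
        if params.paired:
            yield FastqRead(base + "/1", mate1, chrom, start, frag_len, 1)
            mate2_src = reverse_complement(fragment[-params.read_len :])
            mate2 = _apply_errors(mate2_src, rng, params.error_rate)
            yield FastqRead(base + "/2", mate2, chrom, start, frag_len, 2)
        else:
            yield FastqRead(base, mate1, chrom, start, frag_len, 1)


def write_fastq(
    reads: Iterable[FastqRead],
    path1: str | Path,
    path2: str | Path | None = None,
) -> tuple[int, int]:
    """Write reads to FASTQ (gzip if the path ends in .gz).

    Paired mates go to ``path2`` when given, otherwise interleaved into
    ``path1``.  Returns (reads written to file 1, to file 2).
    """

    def _open(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    n1 = n2 = 0
    fh1 = _open(path1)
    fh2 = _open(path2) if path2 is not None else None
    try:
        for read in reads:
            if fh2 is not None and read.mate == 2:
                fh2.write(read.fastq_lines())
                n2 += 1
            else:
                fh1.write(read.fastq_lines())
                n1 += 1
    finally:
        fh1.close()
        if fh2 is not None:
            fh2.close()
    return n1, n2


def origin_depth(
    reads: Iterable[FastqRead], chrom_lengths: dict[str, int], read_len: int
) -> dict[str, np.ndarray]:
    """Per-base depth implied by each read's recorded origin.

    Mate 1 covers ``[frag_start, frag_start + read_len)``; mate 2 covers the
    last ``read_len`` bases of its fragment.  With error_rate 0 each read is
    an exact substring at these coordinates (self-consistency), so this is
    the depth an exact aligner would report.
    """
    depth = {c: np.zeros(l, dtype=np.int64) for c, l in chrom_lengths.items()}
    for read in reads:
        if read.mate == 1:
            s = read.frag_start
        else:
            s = read.frag_start + read.frag_len - read_len
        depth[read.chrom][s : s + read_len] += 1
    return depth


def exact_match_depth(
    reads: Iterable[FastqRead], genome: SequenceSet
) -> dict[str, np.ndarray]:
    """Per-base depth from exact-match placement of reads onto ``genome``.

    Each read is searched on both strands; every exact occurrence increments
    depth over its span.  Intended for error-free fixture reads aligned back
    to short query sequences (e.g. a TE library); not a read mapper.
    """
    depth = {name: np.zeros(len(seq), dtype=np.int64) for name, seq in genome.items()}
    for read in reads:
        queries = (read.seq, reverse_complement(read.seq))
        for name, seq in genome.items():
            vec = depth[name]
            for q in queries:
                pos = seq.find(q)
                while pos != -1:
                    vec[pos : pos + len(q)] += 1
                    pos = seq.find(q, pos + 1)
    return depth
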