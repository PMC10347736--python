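"""Readers and writers for every external format the toolkit touches.

All interval-like objects are held internally in BED convention: 0-based,
half-open ``[start, end)``.  GFF input (1-based, inclusive) is shifted on
read; VCF output (1-based) is shifted on write.  Sequences are uppercased
on read and restricted to the nucleotide alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tebench")

NUCLEOTIDES = frozenset("ACGTN")

#: categories accepted in the prediction BED name field
PREDICTION_CATEGORIES = ("reference", "non-reference")


class FormatError(ValueError):
    """Raised when an input file violates its declared format or dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class SequenceSet:
    """Ordered map of sequence name -> uppercase nucleotide string.

    Names are unique, sequences non-empty, alphabet restricted to A/C/G/T/N.
    """

    def __init__(self, sequences: dict[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise FormatError(f"duplicate sequence name: {name!r}")
        seq = seq.upper()
        if not seq:
            raise FormatError(f"empty sequence for record {name!r}")
        if not NUCLEOTIDES.issuperset(seq):
            bad = sorted(set(seq) - NUCLEOTIDES)
            raise FormatError(
                f"non-nucleotide characters {bad} in record {name!r}"
            )
        self._seqs[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self._seqs == other._seqs

    def names(self) -> list[str]:
        return list(self._seqs)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def copy(self) -> "SequenceSet":
        return SequenceSet(dict(self._seqs))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand and free-text label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PredictionRecord:
    """One detector call parsed from the standardized prediction BED dialect.

    ``category`` is ``"reference"`` (a TE shared with the reference assembly)
    or ``"non-reference"`` (a new insertion absent from the reference).
    Coordinates follow the internal 0-based half-open convention.
    """

    chrom: str
    start: int
    end: int
    family: str
    category: str
    strand: str
    method: str
    tsd_len: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid prediction interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.category not in PREDICTION_CATEGORIES:
            raise FormatError(
                f"category {self.category!r} not in {PREDICTION_CATEGORIES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Per-base signal vectors keyed by chromosome (fixed-step origin)."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    step: int = 1

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values.get(chrom, np.zeros(0))


TaxonomyTable = dict  # TE element name -> family name; kept as a plain dict


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased; record order is preserved.  Duplicate names,
    empty records, or characters outside A/C/G/T/N (any case) raise
    :class:`FormatError`.  An empty file yields an empty set with a logged
    warning so that pipeline dry-runs do not abort.
    """
    seqs = SequenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        seqs.add(record.id, str(record.seq))
    if len(seqs) == 0:
        logger.warning("FASTA file %s contains no records", path)
    return seqs


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping TE element name -> family name."""
    taxonomy: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            name, family = fields[0], fields[1]
            if name in taxonomy:
                raise FormatError(f"{path}:{lineno}: duplicate element {name!r}")
            taxonomy[name] = family
    return taxonomy


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, family in taxonomy.items():
            fh.write(f"{name}\t{family}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a generic BED3+ file into intervals (name -> label if present)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, label=label)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def read_predictions_bed(path: str | Path, method_name: str) -> list[PredictionRecord]:
    """Parse a detector prediction BED6 file.

    The name field follows the dialect ``family|category`` with category in
    ``{reference, non-reference}``; extra ``|``-separated fields are ignored.
    Malformed name fields and empty intervals raise :class:`FormatError`
    naming the offending line.
    """
    records: list[PredictionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6, got {len(fields)} columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            parts = name.split("|")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: name field {name!r} must be "
                    f"'family|category' with category in {PREDICTION_CATEGORIES}"
                )
            family, category = parts[0], parts[1]
            if category not in PREDICTION_CATEGORIES:
                raise FormatError(
                    f"{path}:{lineno}: category {category!r} not in "
                    f"{PREDICTION_CATEGORIES}"
                )
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            records.append(
                PredictionRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    family=family,
                    category=category,
                    strand=strand,
                    method=method_name,
                )
            )
    return records


def write_predictions_bed(records: Iterable[PredictionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t"
                f"{rec.family}|{rec.category}\t0\t{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF
# ---------------------------------------------------------------------------


def read_gff(path: str | Path) -> list[GenomicInterval]:
    """Read GFF3 features as intervals, converting 1-based inclusive
    coordinates to the internal 0-based half-open convention (start - 1)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, start, end = fields[0], int(fields[3]), int(fields[4])
            strand = fields[6] if fields[6] in ("+", "-") else "."
            label = _gff_attribute(fields[8], "ID") or fields[2]
            try:
                intervals.append(
                    GenomicInterval(chrom, start - 1, end, strand=strand, label=label)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def _gff_attribute(attributes: str, key: str) -> str | None:
    for item in attributes.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def write_gff(intervals: Iterable[GenomicInterval], path: str | Path,
              source: str = "tebench", feature: str = "transposable_element") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={iv.label or feature}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##ALT=<ID=INS:ME,Description="Mobile element insertion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=MEINFO,Number=1,Type=String,Description="Mobile element family">
##INFO=<ID=TSDLEN,Number=1,Type=Integer,Description="Target site duplication length">
##INFO=<ID=METHOD,Number=1,Type=String,Description="Detection method">
"""


def write_vcf(records: Iterable[PredictionRecord], reference: SequenceSet,
              path: str | Path) -> None:
    """Write non-reference insertion predictions as minimal VCF 4.2.

    One line per non-reference record; POS is the 1-based start; the ALT is
    the symbolic mobile-element allele ``<INS:ME:FAMILY>``; INFO carries END,
    the TSD length when known, and the calling method.  Reference-category
    records are skipped.  A record on a chromosome absent from ``reference``
    is an error.
    """
    records = list(records)
    for rec in records:
        if rec.chrom not in reference:
            raise FormatError(f"chromosome {rec.chrom!r} absent from reference")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            if rec.category != "non-reference":
                continue
            ref_base = reference[rec.chrom][rec.start]
            info = [f"SVTYPE=INS", f"END={rec.end}", f"MEINFO={rec.family}"]
            if rec.tsd_len is not None:
                info.append(f"TSDLEN={rec.tsd_len}")
            info.append(f"METHOD={rec.method}")
            fh.write(
                f"{rec.chrom}\t{rec.start + 1}\t.\t{ref_base}\t"
                f"<INS:ME:{rec.family}>\t.\tPASS\t{';'.join(info)}\n"
            )


# ---------------------------------------------------------------------------
# Fixed-step WIG
# ---------------------------------------------------------------------------


def read_wig(path: str | Path) -> SignalTrack:
    """Read a fixedStep WIG file into per-base signal vectors.

    Only the fixedStep dialect is supported.  Each declared value occupies
    ``span`` bases (default 1) starting at its position; positions before the
    declared start and gaps between blocks are filled with 0.  WIG positions
    are 1-based; vectors are indexed from base 0.
    """
    chrom_vals: dict[str, list[float]] = {}
    chrom = None
    pos = 0  # 0-based next write position
    step = 1
    span = 1
    track_step = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("variableStep"):
                raise FormatError(
                    f"{path}:{lineno}: variableStep WIG is not supported "
                    "(fixedStep only)"
                )
            if line.startswith("fixedStep"):
                decl = dict(
                    item.split("=", 1) for item in line.split()[1:] if "=" in item
                )
                chrom = decl.get("chrom")
                if chrom is None:
                    raise FormatError(f"{path}:{lineno}: fixedStep without chrom")
                start = int(decl.get("start", 1))
                step = int(decl.get("step", 1))
                span = int(decl.get("span", 1))
                if step < 1:
                    raise FormatError(f"{path}:{lineno}: step must be >= 1")
                if span < 1 or span > step:
                    raise FormatError(f"{path}:{lineno}: span must be in [1, step]")
                if start < 1:
                    raise FormatError(f"{path}:{lineno}: start must be >= 1")
                pos = start - 1
                chrom_vals.setdefault(chrom, [])
                if track_step is None:
                    track_step = step
                continue
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: data before fixedStep header")
            value = float(line)
            vec = chrom_vals[chrom]
            if pos > len(vec):
                vec.extend([0.0] * (pos - len(vec)))  # zero fill gap
            end = pos + span
            if end > len(vec):
                vec.extend([0.0] * (end - len(vec)))
            for i in range(pos, end):
                vec[i] = value
            pos += step
    return SignalTrack(
        values={c: np.asarray(v, dtype=float) for c, v in chrom_vals.items()},
        step=track_step or 1,
    )


def write_wig(track: SignalTrack, path: str | Path) -> None:
    """Write a per-base (step 1) fixedStep WIG file."""
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            for value in vec:
                fh.write(f"{value:g}\n")
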