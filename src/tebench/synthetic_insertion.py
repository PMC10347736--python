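"""Construction of single-insertion synthetic genomes with target-site
duplications (TSDs).

Each replicate genome is the unmodified reference carrying exactly one
additional TE copy.  Integration of an LTR retrotransposon duplicates a
short stretch of host sequence (5 bp for yeast Ty elements) on both flanks
of the element; the synthetic chromosome is therefore built as

    reference[:p + tsd_len] + TE + reference[p:]

so that the ``tsd_len`` bases starting at the insertion point ``p`` appear
once on each side of the inserted element.  Ground truth is the interval
``[p, p + tsd_len)`` in reference coordinates — the span detectors that
report the TSD are expected to return.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    FormatError,
    GenomicInterval,
    SequenceSet,
    reverse_complement,
)


class ConfigurationError(ValueError):
    """Raised when a placement model or insertion request is infeasible."""


STRAND_POLICIES = ("always_plus", "always_minus", "random")


@dataclass(frozen=True)
class InsertionTruth:
    """The single synthetic insertion of one replicate, in reference coords.

    The truth interval is ``[insert_pos, insert_pos + tsd_len)`` — the
    duplicated target site.
    """

    chrom: str
    insert_pos: int
    tsd_len: int
    te_name: str
    family: str
    strand: str
    replicate_id: int = 0

    def __post_init__(self):
        if self.insert_pos < 0 or self.tsd_len < 0:
            raise ConfigurationError("insert_pos and tsd_len must be >= 0")
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"invalid strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.insert_pos

    @property
    def end(self) -> int:
        return self.insert_pos + self.tsd_len


@dataclass
class PlacementModel:
    """Where insertions may land.

    ``permissible_sites`` draws uniformly per-base over the union of the
    given intervals (optionally family-labeled, tying a site to a family).
    ``random_nonrepetitive`` draws uniformly over the genome minus the given
    excluded (repeat) intervals.
    """

    mode: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("permissible_sites", "random_nonrepetitive"):
            raise ConfigurationError(f"unknown placement mode {self.mode!r}")
        if self.mode == "permissible_sites" and not self.intervals:
            raise ConfigurationError(
                "permissible_sites mode requires at least one interval"
            )


def _allowed_intervals(
    model: PlacementModel, reference: SequenceSet, tsd_len: int
) -> list[GenomicInterval]:
    """Resolve the allowed insertion space, clipped so a complete TSD exists
    (no insertion within ``tsd_len`` bases of a chromosome end)."""
    lengths = reference.lengths()
    if model.mode == "permissible_sites":
        candidates = model.intervals
    else:
        # genome minus excluded intervals, per chromosome
        candidates = []
        excluded: dict[str, list[tuple[int, int]]] = {}
        for iv in model.intervals:
            excluded.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, length in lengths.items():
            cursor = 0
            for start, end in sorted(excluded.get(chrom, [])):
                if start > cursor:
                    candidates.append(GenomicInterval(chrom, cursor, start))
                cursor = max(cursor, end)
            if cursor < length:
                candidates.append(GenomicInterval(chrom, cursor, length))
    allowed = []
    for iv in candidates:
        if iv.chrom not in reference:
            raise ConfigurationError(
                f"placement interval on unknown chromosome {iv.chrom!r}"
            )
        hi = min(iv.end, lengths[iv.chrom] - tsd_len)
        if iv.start < hi:
            allowed.append(
                GenomicInterval(iv.chrom, iv.start, hi, strand=iv.strand,
                                label=iv.label)
            )
    return allowed


def replicate_rng(seed: int, replicate_id: int) -> np.random.Generator:
    """Deterministic per-replicate RNG stream from (global seed, replicate)."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate_id)))


def sample_insertion_site(
    model: PlacementModel,
    library: SequenceSet,
    taxonomy: dict[str, str],
    tsd_len: int,
    strand_policy: str = "always_plus",
    replicate_id: int = 0,
    reference: SequenceSet | None = None,
) -> InsertionTruth:
    """Draw one insertion site, element, and strand for a replicate.

    The position is uniform per-base over the allowed space (length-weighted
    across intervals).  When the chosen site carries a family label, the TE
    element is drawn from that family; otherwise uniformly over library
    elements.  Fully reproducible given ``model.seed`` and ``replicate_id``.
    """
    if len(library) == 0:
        raise ConfigurationError("TE library is empty")
    if strand_policy not in STRAND_POLICIES:
        raise ConfigurationError(f"unknown strand_policy {strand_policy!r}")
    if reference is None:
        raise ConfigurationError("a reference SequenceSet is required")

    allowed = _allowed_intervals(model, reference, tsd_len)
    if not allowed:
        raise ConfigurationError("allowed insertion space is empty")

    rng = replicate_rng(model.seed, replicate_id)
    weights = np.array([len(iv) for iv in allowed], dtype=float)
    idx = rng.choice(len(allowed), p=weights / weights.sum())
    site = allowed[idx]
    pos = int(site.start + rng.integers(0, len(site)))

    names = library.names()
    if site.label and site.label != ".":
        candidates = [n for n in names if taxonomy.get(n) == site.label]
        if not candidates:
            raise ConfigurationError(
                f"no library element in family {site.label!r} for labeled site"
            )
    else:
        candidates = names
    te_name = candidates[int(rng.integers(0, len(candidates)))]

    if strand_policy == "always_plus":
        strand = "+"
    elif strand_policy == "always_minus":
        strand = "-"
    else:
        strand = "+" if rng.integers(0, 2) == 0 else "-"

    family = taxonomy.get(te_name)
    if family is None:
        raise ConfigurationError(f"element {te_name!r} missing from taxonomy")
    return InsertionTruth(
        chrom=site.chrom,
        insert_pos=pos,
        tsd_len=tsd_len,
        te_name=te_name,
        family=family,
        strand=strand,
        replicate_id=replicate_id,
    )


def build_synthetic_genome(
    reference: SequenceSet, truth: InsertionTruth, library: SequenceSet
) -> SequenceSet:
    """Insert the TE (with its TSD) into a copy of the reference.

    The modified chromosome is ``ref[:p+tsd] + TE' + ref[p:]`` where ``TE'``
    is the library sequence, reverse-complemented for minus-strand
    insertions.  All other chromosomes are unchanged, so the total length
    grows by exactly ``len(TE) + tsd_len`` and the ``tsd_len`` bases flanking
    the element on both sides are identical.
    """
    if truth.chrom not in reference:
        raise ConfigurationError(f"unknown chromosome {truth.chrom!r}")
    if truth.te_name not in library:
        raise ConfigurationError(f"element {truth.te_name!r} not in library")
    chrom_seq = reference[truth.chrom]
    p, tsd = truth.insert_pos, truth.tsd_len
    if p + tsd > len(chrom_seq):
        raise ConfigurationError(
            f"insertion at {p} with TSD {tsd} exceeds chromosome length "
            f"{len(chrom_seq)}"
        )
    te_seq = library[truth.te_name]
    if truth.strand == "-":
        te_seq = reverse_complement(te_seq)
    new_chrom = chrom_seq[: p + tsd] + te_seq + chrom_seq[p:]
    out = SequenceSet()
    for name, seq in reference.items():
        out.add(name, new_chrom if name == truth.chrom else seq)
    return out


def remove_insertion(
    synthetic: SequenceSet, truth: InsertionTruth, library: SequenceSet
) -> SequenceSet:
    """Invert :func:`build_synthetic_genome`: remove the TE and one TSD copy,
    reconstructing the reference exactly."""
    te_len = len(library[truth.te_name])
    p, tsd = truth.insert_pos, truth.tsd_len
    chrom_seq = synthetic[truth.chrom]
    restored = chrom_seq[: p + tsd] + chrom_seq[p + tsd + te_len + tsd :]
    out = SequenceSet()
    for name, seq in synthetic.items():
        out.add(name, restored if name == truth.chrom else seq)
    return out


# ---------------------------------------------------------------------------
# Truth BED round trip
# ---------------------------------------------------------------------------

_TRUTH_SUFFIX = "truth"
_ZERO_TSD_FLAG = "zero-tsd"


def write_truth(truth: InsertionTruth, path: str | Path) -> None:
    """Write ground truth as one BED6 line:
    ``chrom  p  p+tsd_len  family|non-reference|truth  0  strand``.

    A zero-length TSD would produce an empty BED interval, which parsers
    reject; it is written as ``[p, p+1)`` with a ``zero-tsd`` flag appended
    to the name so the reader can restore the true interval.
    """
    start, end = truth.start, truth.end
    name = f"{truth.family}|non-reference|{_TRUTH_SUFFIX}"
    if truth.tsd_len == 0:
        end = start + 1
        name += f"|{_ZERO_TSD_FLAG}"
    with open(path, "w") as fh:
        fh.write(f"{truth.chrom}\t{start}\t{end}\t{name}\t0\t{truth.strand}\n")


def read_truth(path: str | Path, te_name: str = "", replicate_id: int = 0) -> InsertionTruth:
    """Parse a truth BED written by :func:`write_truth`."""
    with open(path) as fh:
        lines = [l for l in (line.strip() for line in fh) if l]
    if len(lines) != 1:
        raise FormatError(f"truth BED {path} must contain exactly one record")
    fields = lines[0].split("\t")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    parts = fields[3].split("|")
    family = parts[0]
    tsd_len = 0 if _ZERO_TSD_FLAG in parts else end - start
    return InsertionTruth(
        chrom=chrom,
        insert_pos=start,
        tsd_len=tsd_len,
        te_name=te_name or family,
        family=family,
        strand=fields[5],
        replicate_id=replicate_id,
    )
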