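"""Depth-of-coverage TE copy-number estimation.

Copy number of a TE family is estimated as the mean read depth over the
canonical (query) TE sequence divided by the mean depth in non-repetitive
regions of the genome.  A single-copy sequence then scores ~1, a family
with k genomic copies collapsing onto one query scores ~k.  Query termini
are trimmed (default: one read length) before averaging, because alignment
drop-off at the ends of a short reference deflates edge depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .formats_io import GenomicInterval


@dataclass
class DepthProfile:
    """Per-base read depth over one TE query sequence."""

    te_name: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class CopyNumberEstimate:
    te_name: str
    family: str
    mean_depth: float
    normalization_depth: float
    copy_number: float
    edge_trim: int


def depth_from_alignments(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    query_lengths: Mapping[str, int],
) -> dict[str, DepthProfile]:
    """Per-base depth over each query from a SAM file or record iterable.

    ``depth[i]`` counts primary, mapped alignments whose reference span
    covers base i; secondary and supplementary records are ignored to avoid
    double counting multi-mappers.  Alignment to a query not listed in
    ``query_lengths`` is an error; input with no mapped records yields
    all-zero profiles with a warning.
    """
    import logging

    depth = {
        name: np.zeros(length, dtype=np.int64)
        for name, length in query_lengths.items()
    }
    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        records: Iterable[pysam.AlignedSegment] = handle
    else:
        records = alignments
    n_counted = 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        name = rec.reference_name
        if name not in depth:
            raise ValueError(f"alignment to unknown query {name!r}")
        start = rec.reference_start
        end = rec.reference_end if rec.reference_end is not None else start
        vec = depth[name]
        vec[max(0, start) : min(len(vec), end)] += 1
        n_counted += 1
    if n_counted == 0:
        logging.getLogger("tebench").warning(
            "no mapped primary alignments; depth profiles are all zero"
        )
    return {name: DepthProfile(name, vec) for name, vec in depth.items()}


def depth_from_table(path: str | Path) -> dict[str, DepthProfile]:
    """Read per-base depth profiles from a TSV (columns: name, pos, depth)."""
    table = pd.read_csv(path, sep="\t", names=["name", "pos", "depth"],
                        comment="#")
    profiles = {}
    for name, group in table.groupby("name", sort=False):
        length = int(group["pos"].max()) + 1
        vec = np.zeros(length, dtype=np.int64)
        vec[group["pos"].to_numpy()] = group["depth"].to_numpy()
        profiles[name] = DepthProfile(str(name), vec)
    return profiles


def copy_number(
    profile: DepthProfile,
    normalization_depth: float,
    edge_trim: int,
    family: str | None = None,
) -> CopyNumberEstimate:
    """Copy number = mean(depth[edge_trim : L - edge_trim]) / normalization."""
    if normalization_depth <= 0:
        raise ValueError("normalization depth must be > 0")
    length = len(profile)
    if 2 * edge_trim >= length:
        raise ValueError(
            f"edge_trim {edge_trim} leaves no interior of query length {length}"
        )
    core = profile.depth[edge_trim : length - edge_trim]
    mean_depth = float(np.mean(core))
    return CopyNumberEstimate(
        te_name=profile.te_name,
        family=family or profile.te_name,
        mean_depth=mean_depth,
        normalization_depth=float(normalization_depth),
        copy_number=mean_depth / normalization_depth,
        edge_trim=edge_trim,
    )


def unique_region_depth(
    depth_by_chrom: Mapping[str, np.ndarray] | str | Path,
    unique_intervals: Iterable[GenomicInterval],
    chrom_lengths: Mapping[str, int] | None = None,
) -> float:
    """Mean per-base depth over the union of non-repetitive intervals.

    Accepts either precomputed per-chromosome depth vectors or a SAM path of
    alignments to the reference (requires ``chrom_lengths``).
    """
    intervals = list(unique_intervals)
    if not intervals:
        raise ValueError("unique interval set is empty")
    if isinstance(depth_by_chrom, (str, Path)):
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required with SAM input")
        profiles = depth_from_alignments(depth_by_chrom, chrom_lengths)
        depth_by_chrom = {name: prof.depth for name, prof in profiles.items()}
    total = 0.0
    n = 0
    for iv in intervals:
        vec = depth_by_chrom.get(iv.chrom)
        if vec is None:
            raise ValueError(f"no depth for chromosome {iv.chrom!r}")
        segment = vec[iv.start : iv.end]
        total += float(np.sum(segment))
        n += len(segment)
    if n == 0:
        raise ValueError("unique intervals cover zero bases")
    return total / n


def copy_number_table(
    estimates: Iterable[CopyNumberEstimate],
) -> pd.DataFrame:
    rows = [
        {
            "te_name": e.te_name,
            "family": e.family,
            "mean_depth": e.mean_depth,
            "normalization_depth": e.normalization_depth,
            "copy_number": e.copy_number,
            "edge_trim": e.edge_trim,
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "te_name",
            "family",
            "mean_depth",
            "normalization_depth",
            "copy_number",
            "edge_trim",
        ],
    )


def write_depth_tsv(profiles: Mapping[str, DepthProfile], path: str | Path) -> None:
    """Per-base depth TSV (name, pos, depth) for plotting or re-import."""
    with open(path, "w") as fh:
        for name, prof in profiles.items():
            for pos, d in enumerate(prof.depth):
                fh.write(f"{name}\t{pos}\t{int(d)}\n")
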