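"""Deterministic toy input bundles.

Generates every file the toolkit consumes, at desk scale, with no
downloads: a random reference genome with planted full-length TE copies,
a canonical TE library with taxonomy, permissible insertion sites placed
upstream of toy tRNA genes (emulating the Ty targeting preference of
yeast), non-repetitive (unique) regions disjoint from all planted TEs, tRNA
gene/TSS annotations, a fixed-step nucleosome-like occupancy track, and a
ready-to-run experiment configuration.

Fixture genomes are i.i.d. nucleotide sequences at the requested GC with
planted repeats — no attempt at realistic k-mer structure; that suffices to
exercise every operation deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    GenomicInterval,
    SequenceSet,
    SignalTrack,
    write_bed,
    write_fasta,
    write_gff,
    write_taxonomy,
    write_wig,
)


class FixtureError(ValueError):
    """Raised when the requested fixture cannot be packed into the genome."""


@dataclass
class FixtureSpec:
    """Shape of a toy input bundle."""

    n_chroms: int = 2
    chrom_length: int = 50_000
    n_te_families: int = 3
    te_length_range: tuple[int, int] = (1000, 1200)
    n_trna_genes: int = 6
    gc_fraction: float = 0.40
    seed: int = 0
    #: planted full-length copies per family; family 1 gets 3 copies by
    #: default so depth-based copy-number recovery can be tested
    planted_copies: dict[str, int] = field(default_factory=dict)
    trna_length: int = 72
    nucleosome_period: int = 165

    def __post_init__(self):
        if min(self.n_chroms, self.n_te_families, self.n_trna_genes) < 1:
            raise FixtureError("all counts must be >= 1")
        if self.chrom_length < 10 * self.te_length_range[1]:
            raise FixtureError(
                "chromosome length must be >= 10x the longest TE"
            )
        if not self.planted_copies:
            self.planted_copies = {
                f"Ty{chr(ord('A') + i)}": (3 if i == 0 else 1)
                for i in range(self.n_te_families)
            }

    @property
    def family_names(self) -> list[str]:
        return [f"Ty{chr(ord('A') + i)}" for i in range(self.n_te_families)]


@dataclass
class FixtureBundle:
    """Paths and in-memory truth for one generated fixture."""

    root: Path
    reference_fasta: Path
    te_library_fasta: Path
    taxonomy_tsv: Path
    te_annotation_gff: Path
    permissible_bed: Path
    unique_regions_bed: Path
    trna_genes_bed: Path
    trna_tss_bed: Path
    occupancy_wig: Path
    config_json: Path
    reference: SequenceSet
    library: SequenceSet
    taxonomy: dict[str, str]
    te_annotations: list[GenomicInterval]
    unique_regions: list[GenomicInterval]
    trna_genes: list[GenomicInterval]
    planted_copies: dict[str, int]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write a complete toy input bundle under ``out_dir``.

    Deterministic given ``spec.seed``.  Planted TE copies are exact copies
    of the library sequences; unique regions are carved from the background
    between features with a 50-bp margin so they never touch a planted TE.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    families = spec.family_names

    library = SequenceSet()
    for fam in families:
        te_len = int(rng.integers(*spec.te_length_range))
        library.add(fam, _random_sequence(rng, te_len, spec.gc_fraction))
    taxonomy = {fam: fam for fam in families}

    # features to plant: (kind, name, sequence length, strand)
    features: list[tuple[str, str, int, str]] = []
    for fam in families:
        for _ in range(spec.planted_copies.get(fam, 0)):
            features.append(("te", fam, len(library[fam]), "+"))
    for i in range(spec.n_trna_genes):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        features.append(("trna", f"tRNA-{i + 1}", spec.trna_length, strand))
    rng.shuffle(features)

    # round-robin assignment of features to chromosomes
    per_chrom: list[list[tuple[str, str, int, str]]] = [
        [] for _ in range(spec.n_chroms)
    ]
    for i, feat in enumerate(features):
        per_chrom[i % spec.n_chroms].append(feat)

    min_gap = 1500  # background between features: room for unique regions
    reference = SequenceSet()
    te_annotations: list[GenomicInterval] = []
    trna_genes: list[GenomicInterval] = []
    unique_regions: list[GenomicInterval] = []
    permissible: list[GenomicInterval] = []

    for c in range(spec.n_chroms):
        chrom = f"chr{c + 1}"
        feats = per_chrom[c]
        feat_total = sum(f[2] for f in feats)
        bg_total = spec.chrom_length - feat_total
        n_gaps = len(feats) + 1
        if bg_total < n_gaps * min_gap:
            raise FixtureError(
                f"cannot pack {len(feats)} features of {feat_total} bp into "
                f"{chrom} of length {spec.chrom_length}"
            )
        # split background into n_gaps segments, each >= min_gap
        extra = bg_total - n_gaps * min_gap
        cuts = np.sort(rng.integers(0, extra + 1, size=n_gaps - 1))
        gap_lens = np.diff(np.concatenate([[0], cuts, [extra]])) + min_gap
        parts: list[str] = []
        pos = 0
        for i, (kind, name, length, strand) in enumerate(feats):
            bg = _random_sequence(rng, int(gap_lens[i]), spec.gc_fraction)
            parts.append(bg)
            pos += len(bg)
            start, end = pos, pos + length
            if kind == "te":
                parts.append(library[name])
                te_annotations.append(
                    GenomicInterval(chrom, start, end, strand="+", label=name)
                )
            else:
                parts.append(_random_sequence(rng, length, spec.gc_fraction))
                trna_genes.append(
                    GenomicInterval(chrom, start, end, strand=strand, label=name)
                )
                # permissible window upstream of the tRNA gene, w.r.t. strand
                if strand == "+":
                    lo, hi = start - 700, start - 100
                else:
                    lo, hi = end + 100, end + 700
                permissible.append(
                    GenomicInterval(chrom, max(0, lo), hi, strand="+", label=".")
                )
            pos = end
        parts.append(_random_sequence(rng, int(gap_lens[-1]), spec.gc_fraction))
        reference.add(chrom, "".join(parts))
        assert len(reference[chrom]) == spec.chrom_length

    # unique regions: interiors of inter-feature background, margin 50 bp
    for c in range(spec.n_chroms):
        chrom = f"chr{c + 1}"
        occupied = sorted(
            [(iv.start, iv.end) for iv in te_annotations + trna_genes
             if iv.chrom == chrom]
        )
        cursor = 0
        for start, end in occupied + [(spec.chrom_length, spec.chrom_length)]:
            lo, hi = cursor + 50, start - 50
            if hi - lo >= 400:
                unique_regions.append(GenomicInterval(chrom, lo, hi, label="unique"))
            cursor = end

    # nucleosome-like occupancy: cosine of the nucleosome repeat length
    track = SignalTrack(
        values={
            chrom: 1.0
            + np.cos(
                2 * np.pi * np.arange(spec.chrom_length) / spec.nucleosome_period
            )
            for chrom in reference.names()
        },
        step=1,
    )

    paths = {
        "reference_fasta": out / "reference.fasta",
        "te_library_fasta": out / "te_library.fasta",
        "taxonomy_tsv": out / "taxonomy.tsv",
        "te_annotation_gff": out / "reference_TEs.gff",
        "permissible_bed": out / "permissible_sites.bed",
        "unique_regions_bed": out / "unique_regions.bed",
        "trna_genes_bed": out / "trna_genes.bed",
        "trna_tss_bed": out / "trna_tss.bed",
        "occupancy_wig": out / "occupancy.wig",
        "config_json": out / "config.json",
    }
    write_fasta(reference, paths["reference_fasta"])
    write_fasta(library, paths["te_library_fasta"])
    write_taxonomy(taxonomy, paths["taxonomy_tsv"])
    write_gff(te_annotations, paths["te_annotation_gff"])
    write_bed(permissible, paths["permissible_bed"])
    write_bed(unique_regions, paths["unique_regions_bed"])
    write_bed(trna_genes, paths["trna_genes_bed"])
    tss_intervals = [
        GenomicInterval(
            g.chrom,
            g.start if g.strand == "+" else g.end - 1,
            (g.start + 1) if g.strand == "+" else g.end,
            strand=g.strand,
            label=g.label,
        )
        for g in trna_genes
    ]
    write_bed(tss_intervals, paths["trna_tss_bed"])
    write_wig(track, paths["occupancy_wig"])

    config = {
        "reference_fasta": str(paths["reference_fasta"]),
        "te_library_fasta": str(paths["te_library_fasta"]),
        "taxonomy_tsv": str(paths["taxonomy_tsv"]),
        "placement": {
            "mode": "permissible_sites",
            "sites_bed": str(paths["permissible_bed"]),
        },
        "n_replicates": 3,
        "tsd_len": 5,
        "strand_policy": "always_plus",
        "windows": [0, 5, 100, 300, 500],
        "coverages": [3, 6, 12, 25, 50, 100],
        "reads": {
            "read_len": 100,
            "paired": True,
            "frag_mean": 300,
            "frag_sd": 50,
            "error_rate": 0.001,
        },
        "seed": int(spec.seed),
        "detectors": {},
        "output_dir": str(out / "results"),
    }
    with open(paths["config_json"], "w") as fh:
        json.dump(config, fh, indent=2)
        fh.write("\n")

    return FixtureBundle(
        root=out,
        reference=reference,
        library=library,
        taxonomy=taxonomy,
        te_annotations=te_annotations,
        unique_regions=unique_regions,
        trna_genes=trna_genes,
        planted_copies=dict(spec.planted_copies),
        **{k: v for k, v in paths.items()},
    )
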