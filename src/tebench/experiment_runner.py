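"""End-to-end benchmark driver.

Reads a JSON experiment configuration, generates single-insertion synthetic
genomes and WGS read sets across a fold-coverage grid, obtains detector
predictions through adapters (command templates, prediction directories, or
in-process callables), and aggregates the evaluator's scoring into tidy CSV
tables.

Detector execution is fully abstracted: the toolkit never installs a
detector.  An adapter receives a per-replicate context (paths to the
synthetic FASTA, the FASTQ files, the truth BED) and returns prediction
records.  A failed adapter invocation is retried once, then recorded as a
replicate failure without aborting the run.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluator
from .evaluator import DEFAULT_WINDOWS, ReplicateResult, classify_replicate
from .formats_io import (
    FormatError,
    PredictionRecord,
    SequenceSet,
    read_bed,
    read_fasta,
    read_predictions_bed,
    read_taxonomy,
    write_fasta,
)
from .read_sim import ReadSimParams, simulate_reads, write_fastq
from .synthetic_insertion import (
    ConfigurationError,
    InsertionTruth,
    PlacementModel,
    STRAND_POLICIES,
    build_synthetic_genome,
    sample_insertion_site,
    write_truth,
)

logger = logging.getLogger("tebench")

DEFAULT_COVERAGES = (3, 6, 12, 25, 50, 100)
DEFAULT_TSD_LEN = 5

_TOP_KEYS = {
    "reference_fasta",
    "te_library_fasta",
    "taxonomy_tsv",
    "placement",
    "n_replicates",
    "tsd_len",
    "strand_policy",
    "windows",
    "coverages",
    "reads",
    "seed",
    "detectors",
    "output_dir",
}
_PLACEMENT_KEYS = {"mode", "sites_bed", "excluded_bed"}
_READS_KEYS = {"read_len", "paired", "frag_mean", "frag_sd", "error_rate"}
_DETECTOR_KEYS = {"command", "predictions_dir"}


@dataclass
class ExperimentConfig:
    """Validated experiment configuration with all defaults filled."""

    reference: SequenceSet
    library: SequenceSet
    taxonomy: dict[str, str]
    placement: PlacementModel
    n_replicates: int
    tsd_len: int
    strand_policy: str
    windows: tuple[int, ...]
    coverages: tuple[float, ...]
    read_params: ReadSimParams
    seed: int
    detectors: dict[str, dict]
    output_dir: Path


@dataclass
class ReplicateContext:
    """What an adapter sees for one (replicate, coverage) cell."""

    replicate_id: int
    fold_coverage: float
    genome_fasta: Path
    fastq1: Path
    fastq2: Path | None
    truth_bed: Path
    truth: InsertionTruth
    workdir: Path


Adapter = Callable[[ReplicateContext], list[PredictionRecord]]


def validate_config(raw: dict | str | Path) -> ExperimentConfig:
    """Validate a raw JSON configuration and fill defaults.

    Every referenced file is opened and format-checked; cross-checks verify
    that every library element appears in the taxonomy and that placement
    intervals fall within reference bounds.  Unknown keys are rejected, and
    every failed check is reported with its field path.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a JSON object")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("reference_fasta", "te_library_fasta", "taxonomy_tsv", "placement"):
        if key not in raw:
            raise ConfigurationError(f"{key}: required key missing")

    reference = read_fasta(raw["reference_fasta"])
    if len(reference) == 0:
        raise ConfigurationError("reference_fasta: no sequences")
    library = read_fasta(raw["te_library_fasta"])
    if len(library) == 0:
        raise ConfigurationError("te_library_fasta: no sequences")
    taxonomy = read_taxonomy(raw["taxonomy_tsv"])
    for name in library.names():
        if name not in taxonomy:
            raise ConfigurationError(
                f"taxonomy_tsv: library element {name!r} has no family entry"
            )

    placement_raw = raw["placement"]
    unknown = set(placement_raw) - _PLACEMENT_KEYS
    if unknown:
        raise ConfigurationError(f"placement: unknown keys {sorted(unknown)}")
    mode = placement_raw.get("mode")
    seed = int(raw.get("seed", 0))
    if mode == "permissible_sites":
        intervals = read_bed(placement_raw["sites_bed"])
    elif mode == "random_nonrepetitive":
        intervals = (
            read_bed(placement_raw["excluded_bed"])
            if "excluded_bed" in placement_raw
            else []
        )
    else:
        raise ConfigurationError(f"placement.mode: unknown mode {mode!r}")
    lengths = reference.lengths()
    for iv in intervals:
        if iv.chrom not in lengths:
            raise ConfigurationError(
                f"placement: interval chromosome {iv.chrom!r} not in reference"
            )
        if iv.end > lengths[iv.chrom]:
            raise ConfigurationError(
                f"placement: interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {lengths[iv.chrom]}"
            )
    placement = PlacementModel(mode=mode, intervals=intervals, seed=seed)

    n_replicates = int(raw.get("n_replicates", 1))
    if n_replicates < 1:
        raise ConfigurationError("n_replicates: must be >= 1")
    tsd_len = int(raw.get("tsd_len", DEFAULT_TSD_LEN))
    if tsd_len < 0:
        raise ConfigurationError("tsd_len: must be >= 0")
    strand_policy = raw.get("strand_policy", "always_plus")
    if strand_policy not in STRAND_POLICIES:
        raise ConfigurationError(
            f"strand_policy: must be one of {STRAND_POLICIES}"
        )
    windows = tuple(int(w) for w in raw.get("windows", DEFAULT_WINDOWS))
    if any(w < 0 for w in windows) or not windows:
        raise ConfigurationError("windows: must be a non-empty list of N >= 0")
    coverages = tuple(float(c) for c in raw.get("coverages", DEFAULT_COVERAGES))
    if not coverages or any(c <= 0 for c in coverages):
        raise ConfigurationError("coverages: must be a non-empty list of c > 0")

    reads_raw = dict(raw.get("reads", {}))
    unknown = set(reads_raw) - _READS_KEYS
    if unknown:
        raise ConfigurationError(f"reads: unknown keys {sorted(unknown)}")
    try:
        read_params = ReadSimParams(fold_coverage=coverages[0], seed=seed,
                                    **reads_raw)
    except ValueError as exc:
        raise ConfigurationError(f"reads: {exc}") from exc

    detectors = dict(raw.get("detectors", {}))
    for name, det in detectors.items():
        unknown = set(det) - _DETECTOR_KEYS
        if unknown:
            raise ConfigurationError(
                f"detectors.{name}: unknown keys {sorted(unknown)}"
            )
        if not ({"command", "predictions_dir"} & set(det)):
            raise ConfigurationError(
                f"detectors.{name}: needs 'command' or 'predictions_dir'"
            )

    return ExperimentConfig(
        reference=reference,
        library=library,
        taxonomy=taxonomy,
        placement=placement,
        n_replicates=n_replicates,
        tsd_len=tsd_len,
        strand_policy=strand_policy,
        windows=windows,
        coverages=coverages,
        read_params=read_params,
        seed=seed,
        detectors=detectors,
        output_dir=Path(raw.get("output_dir", "results")),
    )


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------


def truth_echo_adapter(ctx: ReplicateContext) -> list[PredictionRecord]:
    """Oracle predictor: echoes the ground-truth insertion exactly."""
    t = ctx.truth
    end = t.end if t.tsd_len > 0 else t.start + 1
    return [
        PredictionRecord(
            chrom=t.chrom,
            start=t.start,
            end=end,
            family=t.family,
            category="non-reference",
            strand=t.strand,
            method="truth_echo",
        )
    ]


def empty_adapter(ctx: ReplicateContext) -> list[PredictionRecord]:
    """Null predictor: makes no calls."""
    return []


def command_adapter(name: str, template: str) -> Adapter:
    """Adapter that shells out to a detector command template.

    Placeholders ``{fasta}``, ``{fastq1}``, ``{fastq2}`` and ``{out}`` are
    substituted; the command must write a prediction BED (dialect
    ``family|category``) to ``{out}``.
    """

    def run(ctx: ReplicateContext) -> list[PredictionRecord]:
        out_bed = ctx.workdir / f"{name}.bed"
        cmd = template.format(
            fasta=ctx.genome_fasta,
            fastq1=ctx.fastq1,
            fastq2=ctx.fastq2 or "",
            out=out_bed,
        )
        subprocess.run(shlex.split(cmd), check=True)
        return read_predictions_bed(out_bed, name)

    run.__name__ = f"command_adapter[{name}]"
    return run


def prediction_dir_adapter(name: str, directory: str | Path) -> Adapter:
    """Adapter that ingests precomputed prediction BEDs from a directory
    laid out as ``<dir>/cov<coverage>/rep<replicate>.bed``."""

    def run(ctx: ReplicateContext) -> list[PredictionRecord]:
        cov = ctx.fold_coverage
        cov_str = f"{int(cov)}" if float(cov).is_integer() else f"{cov:g}"
        path = Path(directory) / f"cov{cov_str}" / f"rep{ctx.replicate_id}.bed"
        if not path.exists():
            raise FileNotFoundError(path)
        return read_predictions_bed(path, name)

    run.__name__ = f"prediction_dir_adapter[{name}]"
    return run


def _adapters_from_config(config: ExperimentConfig) -> dict[str, Adapter]:
    adapters: dict[str, Adapter] = {}
    for name, det in config.detectors.items():
        if "command" in det:
            adapters[name] = command_adapter(name, det["command"])
        else:
            adapters[name] = prediction_dir_adapter(name, det["predictions_dir"])
    return adapters


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    offsets: pd.DataFrame
    tsd_lengths: pd.DataFrame
    upset: pd.DataFrame
    failures: pd.DataFrame
    replicate_results: dict[str, list[ReplicateResult]] = field(
        default_factory=dict
    )


def run_experiment(
    config: ExperimentConfig,
    adapters: Mapping[str, Adapter] | None = None,
    keep_artifacts: bool = True,
) -> ExperimentResult:
    """Run the full benchmark and write the aggregated CSV tables.

    For each replicate a synthetic genome is drawn once (per-replicate RNG
    stream from the global seed); for each fold-coverage a read set is
    simulated from it and every adapter is invoked.  Adapter failures are
    retried once, then recorded in the failures table.  Byte-identical
    outputs are produced for identical configuration and seed.
    """
    if adapters is None:
        adapters = _adapters_from_config(config)
    if not adapters:
        raise ConfigurationError("no detector adapters configured")
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    per_method: dict[str, list[ReplicateResult]] = {m: [] for m in adapters}
    failures: list[dict] = []
    chrom_names = config.reference.names()

    for rep in range(config.n_replicates):
        truth = sample_insertion_site(
            config.placement,
            config.library,
            config.taxonomy,
            config.tsd_len,
            strand_policy=config.strand_policy,
            replicate_id=rep,
            reference=config.reference,
        )
        synthetic = build_synthetic_genome(config.reference, truth, config.library)
        rep_dir = out_dir / f"rep{rep}"
        rep_dir.mkdir(exist_ok=True)
        fasta_path = rep_dir / "synthetic.fasta"
        truth_path = rep_dir / "truth.bed"
        if keep_artifacts:
            write_fasta(synthetic, fasta_path)
            write_truth(truth, truth_path)

        for cov in config.coverages:
            cov_dir = rep_dir / f"cov{cov:g}"
            cov_dir.mkdir(exist_ok=True)
            # reads seeded per (global seed, replicate, coverage)
            read_seed = int(
                np.random.SeedSequence(
                    (config.seed, rep, int(round(cov * 1000)))
                ).generate_state(1)[0]
                % (2**31)
            )
            params = ReadSimParams(
                read_len=config.read_params.read_len,
                paired=config.read_params.paired,
                frag_mean=config.read_params.frag_mean,
                frag_sd=config.read_params.frag_sd,
                error_rate=config.read_params.error_rate,
                fold_coverage=cov,
                seed=read_seed,
            )
            fq1 = cov_dir / "reads_1.fastq"
            fq2 = cov_dir / "reads_2.fastq" if params.paired else None
            if keep_artifacts:
                write_fastq(simulate_reads(synthetic, params), fq1, fq2)
            ctx = ReplicateContext(
                replicate_id=rep,
                fold_coverage=cov,
                genome_fasta=fasta_path,
                fastq1=fq1,
                fastq2=fq2,
                truth_bed=truth_path,
                truth=truth,
                workdir=cov_dir,
            )
            for method, adapter in adapters.items():
                predictions = _invoke_with_retry(method, adapter, ctx, failures)
                if predictions is None:
                    continue  # recorded failure; replicate skipped
                result = classify_replicate(
                    predictions,
                    truth,
                    windows=config.windows,
                    chrom_names=chrom_names,
                    method=method,
                    fold_coverage=cov,
                )
                per_method[method].append(result)

    all_results = [r for results in per_method.values() for r in results]
    metrics = evaluator.precision_recall(all_results)
    offsets = evaluator.positional_accuracy(all_results)
    tsd_lengths = evaluator.tsd_length_distribution(all_results)
    upset_frames = []
    complete = {
        m: res
        for m, res in per_method.items()
        if len(res) == config.n_replicates * len(config.coverages)
    }
    if complete:
        for cov in config.coverages:
            for window in config.windows:
                frame = evaluator.tp_overlap_matrix(complete, window, cov)
                frame.insert(0, "window", window)
                frame.insert(0, "fold_coverage", cov)
                upset_frames.append(frame)
    upset = (
        pd.concat(upset_frames, ignore_index=True)
        if upset_frames
        else pd.DataFrame(columns=["fold_coverage", "window", "methods",
                                   "degree", "count"])
    )
    failures_df = pd.DataFrame(
        failures, columns=["method", "replicate_id", "fold_coverage", "error"]
    )
    for m, res in per_method.items():
        if not res:
            logger.warning("all replicates failed for method %s", m)

    metrics.to_csv(out_dir / "metrics.csv", index=False)
    offsets.to_csv(out_dir / "offsets.csv", index=False)
    tsd_lengths.to_csv(out_dir / "tsd_lengths.csv", index=False)
    upset.to_csv(out_dir / "upset.csv", index=False)
    failures_df.to_csv(out_dir / "failures.csv", index=False)
    with open(out_dir / "run.log", "w") as fh:
        fh.write(
            f"methods={sorted(adapters)} replicates={config.n_replicates} "
            f"coverages={list(config.coverages)} windows={list(config.windows)} "
            f"seed={config.seed} failures={len(failures)}\n"
        )
    return ExperimentResult(
        metrics=metrics,
        offsets=offsets,
        tsd_lengths=tsd_lengths,
        upset=upset,
        failures=failures_df,
        replicate_results=per_method,
    )


def _invoke_with_retry(
    method: str,
    adapter: Adapter,
    ctx: ReplicateContext,
    failures: list[dict],
) -> list[PredictionRecord] | None:
    for attempt in (1, 2):
        try:
            return adapter(ctx)
        except Exception as exc:  # noqa: BLE001 - adapter code is external
            if attempt == 2:
                logger.warning(
                    "method %s failed twice on replicate %d cov %g: %s",
                    method, ctx.replicate_id, ctx.fold_coverage, exc,
                )
                failures.append(
                    {
                        "method": method,
                        "replicate_id": ctx.replicate_id,
                        "fold_coverage": ctx.fold_coverage,
                        "error": str(exc),
                    }
                )
    return None
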