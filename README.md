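# tebench

A benchmarking toolkit for short-read detectors of non-reference
transposable-element (TE) insertions.

Many tools infer new TE insertions from short-read whole-genome sequencing
by split-read or read-pair evidence, and their accuracy varies widely with
organism, TE family, and sequencing depth. `tebench` implements the
*single synthetic insertion* evaluation design: each replicate genome is an
otherwise-unmodified reference carrying exactly one additional TE copy with
its target-site duplication (TSD), a matching WGS read set is simulated,
and detector calls are scored against the known insertion. The toolkit is
aimed at yeast Ty-style benchmarks (tRNA-promoter-targeted insertions,
5-bp TSDs) but every parameter is configurable.

## What it computes

**Synthetic genomes.** An insertion at reference offset *p* with TSD length
*t* produces the chromosome `ref[:p+t] + TE + ref[p:]`, so the *t* host
bases at *p* flank the element on both sides (the duplicated target site).
Ground truth is the interval `[p, p+t)`. Placement is uniform per-base over
permissible sites (e.g. tRNA promoter windows) or over the genome minus
excluded repeats.

**Read simulation.** Single- or paired-end reads at a requested
fold-coverage *c*: the number of fragments is `round(c·L / (2·ℓ))` for
read length ℓ (paired), fragment lengths are Normal(μ, σ), and each base is
substituted with probability *e*.

**Scoring.** For window sizes N ∈ {0, 5, 100, 300, 500}, a non-reference
call is *within-N* when chromosome, family and strand match and both
|Δstart| ≤ N and |Δend| ≤ N (N = 0 requires identical coordinates). At most
one within-N call per replicate is the true positive; all other
non-reference calls are false positives; a replicate with no within-N call
is a false negative. Summed over replicates,

    recall = TP / (TP + FN)        precision = TP / (TP + FP)

with precision reported as missing (never 0) when a method makes no calls.
Positional-offset distributions, predicted-TSD-length histograms, and
per-method TP overlap tables (UpSet input) are also produced.

**Copy number.** For each canonical TE query, copy number = trimmed mean
read depth over the query / mean depth in user-supplied non-repetitive
regions.

**Targeting profiles.** Insertions are labeled tRNA-proximal when they fall
between 1000 bp upstream and 500 bp downstream of a tRNA gene
(strand-aware); signed distances to the nearest tRNA TSS are negative
upstream / positive downstream; a nucleosome-occupancy track is averaged
over TSS-aligned windows (2 kb upstream to 500 bp downstream); distance
distributions are smoothed with a Gaussian kernel at 0.4× the rule-of-thumb
bandwidth.

## Worked example

```python
import dataclasses
from pathlib import Path
from tebench import (FixtureSpec, make_fixture, validate_config,
                     run_experiment, truth_echo_adapter)
from tebench.experiment_runner import empty_adapter

# deterministic toy inputs: reference, TE library, taxonomy, tRNA genes,
# permissible insertion sites, and a ready-made config.json
bundle = make_fixture(FixtureSpec(seed=4), "demo_inputs")
config = dataclasses.replace(
    validate_config(bundle.config_json),
    n_replicates=5, coverages=(12.0, 50.0), output_dir=Path("demo_results"),
)
result = run_experiment(config, adapters={"oracle": truth_echo_adapter,
                                          "null": empty_adapter})
cols = ["method", "fold_coverage", "window", "TP", "FP", "FN",
        "recall", "precision"]
print(result.metrics[cols].to_string(index=False))
```

prints (abridged):

```
method  fold_coverage  window  TP  FP  FN  recall  precision
  null           12.0       0   0   0   5     0.0        NaN
  null           50.0     500   0   0   5     0.0        NaN
oracle           12.0       0   5   0   0     1.0        1.0
oracle           50.0     500   5   0   0     1.0        1.0
```

The `oracle` adapter echoes the ground truth, so it scores perfect recall
and precision at every window and coverage; the `null` adapter makes no
calls, so recall is 0 and precision is missing (`NaN`) rather than 0 — a
method that stays silent is not double-penalized. A real detector plugs in
as a command template (`{fasta} {fastq1} {fastq2} {out}` placeholders) or a
directory of precomputed prediction BEDs; see
`tebench.experiment_runner.command_adapter`.

The same functionality is exposed on the command line:

```sh
tebench make-fixture --seed 3 --out fix
tebench simulate-genome --config fix/config.json --replicate 0 --out gen
tebench simulate-reads --fasta gen/rep0.fasta --coverage 25 --out reads
tebench evaluate --truth gen/rep0.truth.bed --pred mycalls.bed --out eval
tebench run --config fix/config.json
tebench convert --bed mycalls.bed --reference fix/reference.fasta --out calls.vcf
```

## Layout

- `src/tebench/formats_io.py` — FASTA/BED/GFF/VCF/WIG/TSV readers and
  writers, 0-based half-open coordinates throughout
- `src/tebench/synthetic_insertion.py` — placement models, TSD
  construction, truth records
- `src/tebench/read_sim.py` — wgsim-like read simulator
- `src/tebench/evaluator.py` — within-N scoring and aggregation
- `src/tebench/coverage_copynumber.py` — depth-ratio copy-number estimator
- `src/tebench/targeting_profile.py` — tRNA proximity, TSS distances,
  signal aggregation, kernel densities
- `src/tebench/experiment_runner.py` — JSON config, adapters, full runs
- `src/tebench/fixtures.py` — deterministic toy input bundles

See `docs/methods.md` for the modeling choices and their limitations.
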