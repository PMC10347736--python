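# Methods

## The single-synthetic-insertion design

The toolkit evaluates non-reference TE insertion detectors under the
simplest controlled condition: one new insertion per genome. Each
replicate draws an insertion site, element, and strand; builds a synthetic
genome; simulates a WGS read set; and scores detector output against the
one known truth. Because every replicate contains exactly one true event,
per-replicate TP ∈ {0,1} and FN = 1 − TP, and recall/precision aggregate
by summing TP/FP/FN across replicates before taking ratios. This isolates
detector behavior from confounders of real resequencing panels (multiple
insertions, tandem elements, variable library composition), at the cost of
never exercising interactions between nearby events.

## Target-site duplication construction

Integration of an LTR retrotransposon duplicates a short host motif on
both flanks (5 bp for yeast Ty elements, the toolkit default). With
insertion point `p` and TSD length `t`, the synthetic chromosome is
`ref[:p+t] + TE + ref[p:]`: the `t` bases starting at `p` appear once on
each side of the element, and the truth interval in reference coordinates
is `[p, p+t)` — the span a breakpoint-resolving detector should report.
Two consequences are used as internal checks: total length grows by
exactly `len(TE) + t`, and deleting the element plus one TSD copy restores
the reference byte-identically. Insertions are forbidden within `t` bases
of a chromosome end so a complete TSD always exists. A zero-length TSD is
supported (plain insertion); its truth BED line is padded to `[p, p+1)`
with a `zero-tsd` name flag because BED cannot represent empty intervals.

## Placement models

`permissible_sites` draws the insertion point uniformly *per base* over
the union of the supplied intervals (length-weighted, not per-interval) —
the standard null given no further information. When a site interval
carries a family label, the element is drawn from that family, supporting
family-per-locus designs; otherwise the element is uniform over the
library. `random_nonrepetitive` draws uniformly over the genome minus the
supplied repeat intervals. Per-replicate RNG streams are derived from
(global seed, replicate id), so replicates are independently reproducible
and insensitive to execution order.

## Read simulator

A substitution-only, wgsim-like model: fragments start uniformly along a
chromosome chosen with probability proportional to length; fragment
lengths are Normal(μ=300, σ=50 by default) rounded and *clamped* to
[read length, chromosome length] (clamping rather than rejection keeps the
fragment count, and hence realized coverage, exact); mate 1 is the
fragment 5′ prefix and mate 2 the reverse complement of the 3′ suffix;
each base substitutes to a uniformly chosen different base with
probability `error_rate`; qualities are a constant `I`. Fragment counts
follow from the coverage identity `n = round(c·L / (2ℓ))` (paired). The
model reproduces the sampling variance of shotgun data but none of the
platform artefacts (indels, quality decay, GC bias, duplicates); detectors
sensitive to those will look better here than on real data. An external
simulator can be substituted by writing FASTQ through any other means and
using prediction-directory adapters.

## Scoring rules

A non-reference prediction is *within-N* of the truth when chromosome and
family match, strand matches (a `.` strand matches either in the default
lenient mode, since several detectors omit strand; strict mode is
available), and both |pred_start − truth_start| ≤ N and
|pred_end − truth_end| ≤ N. N = 0 therefore demands identical coordinates.
When several predictions qualify, exactly one — smallest |start offset|,
ties to the smaller start — counts as the TP and all other non-reference
predictions genome-wide are FPs; with none, the replicate is an FN.
Reference-category predictions contribute to mean prediction counts only.
Precision is undefined when a method makes no calls and is reported as
missing, never coerced to 0, to avoid penalizing silence twice. The
tie-break is a deterministic convention chosen for reproducibility; any
single-TP rule gives identical recall, and precision differs only through
which qualifying call is labeled TP (never how many).

Monotonicity (recall non-decreasing in N over nested windows) and the
conservation identities (TP+FN = 1, TP+FP = number of non-reference calls)
are asserted in tests against an independently written exhaustive scorer.

## Copy-number estimator

Copy number of a query TE = mean depth over the query interior divided by
mean depth over user-supplied non-repetitive regions. The interior trims
`edge_trim` bases (default: one read length) from each end, because reads
must lie entirely within the query to align to it, which linearly deflates
depth within one read length of the termini. The estimator assumes the
query is long enough that the trimmed interior still averages over many
read placements; the toolkit's toy elements are 1.0–1.2 kb (real Ty
elements are ~6 kb) so the interior spans ≥ 800 positions. Only primary
mapped alignments are counted, to avoid double-counting multi-mappers.
Solo-LTR versus full-length discrimination is obtained by supplying
internal-region sequences as the query set, not by any special handling.

## Targeting profiles

- Proximity: an insertion is tRNA-proximal when it overlaps a gene
  interval extended 1000 bp upstream and 500 bp downstream *with respect
  to the gene's strand* (for a minus-strand gene, upstream extends to
  higher coordinates). Classification uses gene intervals; distances use
  TSS points — the two anchors serve different questions.
- Signed distance: insertion start minus TSS position, sign flipped for
  minus-strand TSSs, so negative is always upstream of the gene. Duplicate
  calls at the identical (chromosome, start, family) collapse to one
  non-redundant site before profiling.
- Signal aggregation: per-base windows [TSS−2000, TSS+500], reversed for
  minus-strand TSSs, averaged per relative position; truncated windows
  contribute only covered positions (positions covered by no window are
  NaN, not zero).
- Density: Gaussian KDE with bandwidth 0.4 × the rule-of-thumb bandwidth
  `0.9·min(sd, IQR/1.349)·n^(−1/5)` (the default of common density-plot
  routines, including its fallbacks for degenerate spreads). The kernel
  sum is evaluated directly so all-identical inputs degrade to a sharp
  peak instead of a singular covariance error.

## Experiment runner

The JSON configuration is validated eagerly: unknown keys are rejected,
every referenced file is opened and format-checked, library/taxonomy
cross-references and placement bounds are verified, and defaults are
filled (TSD 5 bp; windows {0,5,100,300,500}; coverages
{3,6,12,25,50,100}×). One synthetic genome is drawn per replicate and
shared across coverages, so TP-overlap comparisons across methods and
coverage levels see identical truths; read sets are seeded per
(seed, replicate, coverage). Detector adapters are retried once on
failure, then the cell is recorded in a failures table and the run
continues — a benchmark should degrade, not abort, when one tool crashes.
Outputs are tidy CSVs (metrics, offsets, TSD lengths, UpSet membership,
failures) that are byte-identical for identical configuration and seed.

## Fixture generator

Fixture genomes are i.i.d. nucleotides at a requested GC (default 0.40)
with planted features: full-length TE copies (three identical copies of
the first family by default, so the copy-number estimator has a known
answer), toy tRNA genes with permissible insertion windows placed 100–700
bp upstream on the strand-appropriate side, unique regions carved from
inter-feature background with a 50-bp margin (disjoint from all planted
TEs), and a cosine occupancy track at the nucleosome repeat length
(165 bp). Defaults: 2 chromosomes × 50 kb, 3 families of 1.0–1.2 kb, 6
tRNA genes. The generator makes no attempt at realistic k-mer composition,
repeat fragments, or heterozygosity; consequently passing tests
demonstrate correctness of the machinery, not expected detector
performance on real genomes — real detectors must be benchmarked through
the adapter interface on realistic references.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: 30–100 kb genomes,
coverages up to 50×, 20–100 replicates, 1,000 random scoring instances.
Fragment counts round half-to-even; WIG input supports fixedStep only
(gaps zero-filled, the natural occupancy baseline); all internal intervals
are 0-based half-open with GFF shifted on read and VCF on write; the VCF
writer emits a minimal symbolic-allele schema
(`<INS:ME:FAMILY>` with END/MEINFO/TSDLEN/METHOD INFO keys) that
round-trips through standard VCF parsers.

## Known limitations

One insertion per genome (no excision, tandems, or nested events);
substitution-only read errors; no read mapping (copy-number consumes SAM
from an external mapper, or exact-match placement for error-free fixture
reads); reference-insertion recall is out of scope because the design
never perturbs shared insertions; statistical comparison between methods
(tests, confidence intervals) is left to downstream analysis of the tidy
outputs.
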