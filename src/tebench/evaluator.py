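"""Window-based scoring of detector predictions against single-insertion
ground truth.

Classification rule, per replicate and window size N: a non-reference
prediction qualifies when it is on the truth chromosome, names the truth
family, matches the truth strand (see ``strand_mode``), and both its start
and end coordinates lie within N bases of the truth interval.  N = 0
therefore requires identical start and end coordinates ("exact").  If one
or more predictions qualify, exactly one is the true positive — the one
with the smallest |start offset|, ties broken toward the smaller start —
and every other non-reference prediction genome-wide is a false positive.
If none qualifies the replicate is a false negative.  Reference-category
predictions are tallied but never enter TP/FP/FN.

Recall = TP/(TP+FN) and precision = TP/(TP+FP), with TP/FP/FN summed over
replicates before the ratio.  Precision is *missing* (not 0) when a method
makes no calls at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import PredictionRecord
from .synthetic_insertion import InsertionTruth

DEFAULT_WINDOWS = (0, 5, 100, 300, 500)
STRAND_MODES = ("lenient", "strict")

#: a MetricsSummary is a tidy DataFrame with one row per
#: (method, fold_coverage, window) — see :func:`precision_recall`
MetricsSummary = pd.DataFrame


@dataclass
class ReplicateResult:
    """Per-replicate scoring outcome across all window sizes."""

    method: str
    fold_coverage: float
    replicate_id: int
    tp: dict[int, int] = field(default_factory=dict)
    fp: dict[int, int] = field(default_factory=dict)
    fn: dict[int, int] = field(default_factory=dict)
    n_reference: int = 0
    n_nonreference: int = 0
    #: per window: (pred_start - truth_start, pred_end - truth_end) of the TP
    offsets: dict[int, tuple[int, int]] = field(default_factory=dict)
    #: end - start of every non-reference prediction
    tsd_lengths: list[int] = field(default_factory=list)


def _strand_match(pred_strand: str, truth_strand: str, strand_mode: str) -> bool:
    if strand_mode == "lenient" and pred_strand == ".":
        return True
    return pred_strand == truth_strand


def classify_replicate(
    predictions: Sequence[PredictionRecord],
    truth: InsertionTruth,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    strand_mode: str = "lenient",
    chrom_names: Iterable[str] | None = None,
    method: str | None = None,
    fold_coverage: float = float("nan"),
) -> ReplicateResult:
    """Score one method's predictions on one replicate at every window size."""
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {STRAND_MODES}")
    if chrom_names is not None:
        known = set(chrom_names)
        for pred in predictions:
            if pred.chrom not in known:
                raise ValueError(
                    f"prediction on unknown chromosome {pred.chrom!r}"
                )
    nonref = [p for p in predictions if p.category == "non-reference"]
    n_ref = sum(1 for p in predictions if p.category == "reference")
    result = ReplicateResult(
        method=method or (predictions[0].method if predictions else "unknown"),
        fold_coverage=fold_coverage,
        replicate_id=truth.replicate_id,
        n_reference=n_ref,
        n_nonreference=len(nonref),
        tsd_lengths=[p.length for p in nonref],
    )
    for n in windows:
        qualifying = [
            p
            for p in nonref
            if p.chrom == truth.chrom
            and p.family == truth.family
            and _strand_match(p.strand, truth.strand, strand_mode)
            and abs(p.start - truth.start) <= n
            and abs(p.end - truth.end) <= n
        ]
        if qualifying:
            tp_pred = min(
                qualifying, key=lambda p: (abs(p.start - truth.start), p.start)
            )
            result.tp[n] = 1
            result.fn[n] = 0
            result.fp[n] = len(nonref) - 1
            result.offsets[n] = (
                tp_pred.start - truth.start,
                tp_pred.end - truth.end,
            )
        else:
            result.tp[n] = 0
            result.fn[n] = 1
            result.fp[n] = len(nonref)
    return result


def precision_recall(results: Iterable[ReplicateResult]) -> pd.DataFrame:
    """Aggregate replicate results into recall/precision and mean counts.

    Returns a tidy frame with one row per (method, fold_coverage, window):
    summed TP/FP/FN, recall, precision (NaN where TP+FP = 0), and the mean
    reference / non-reference prediction counts per synthetic genome.
    """
    results = list(results)
    if not results:
        raise ValueError("no replicate results to aggregate")
    rows = []
    keyed: dict[tuple[str, float], list[ReplicateResult]] = {}
    for res in results:
        keyed.setdefault((res.method, res.fold_coverage), []).append(res)
    for (method, cov), group in sorted(keyed.items()):
        windows = sorted(group[0].tp)
        for n in windows:
            tp = sum(r.tp[n] for r in group)
            fp = sum(r.fp[n] for r in group)
            fn = sum(r.fn[n] for r in group)
            recall = tp / (tp + fn) if tp + fn > 0 else np.nan
            precision = tp / (tp + fp) if tp + fp > 0 else np.nan
            rows.append(
                {
                    "method": method,
                    "fold_coverage": cov,
                    "window": n,
                    "n_replicates": len(group),
                    "TP": tp,
                    "FP": fp,
                    "FN": fn,
                    "recall": recall,
                    "precision": precision,
                    "mean_reference": float(
                        np.mean([r.n_reference for r in group])
                    ),
                    "mean_nonreference": float(
                        np.mean([r.n_nonreference for r in group])
                    ),
                    "mean_within_n": float(np.mean([r.tp[n] for r in group])),
                }
            )
    return pd.DataFrame(rows)


def positional_accuracy(
    results: Iterable[ReplicateResult], window: int | None = None
) -> pd.DataFrame:
    """Empirical distribution of signed TP offsets per method.

    Offsets are (predicted - true) start and end coordinates of the replicate
    TP at the given window (default: the widest window scored).
    """
    rows = []
    for res in results:
        n = window if window is not None else max(res.tp)
        if n in res.offsets:
            ds, de = res.offsets[n]
            rows.append(
                {
                    "method": res.method,
                    "fold_coverage": res.fold_coverage,
                    "replicate_id": res.replicate_id,
                    "window": n,
                    "start_offset": ds,
                    "end_offset": de,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "method",
            "fold_coverage",
            "replicate_id",
            "window",
            "start_offset",
            "end_offset",
        ],
    )


def offset_quantiles(
    offsets: pd.DataFrame, qs: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95)
) -> pd.DataFrame:
    """Summary quantiles of start offsets per method."""
    if offsets.empty:
        return pd.DataFrame(columns=["method", *[f"q{int(q*100)}" for q in qs]])
    rows = []
    for method, group in offsets.groupby("method"):
        row = {"method": method}
        for q in qs:
            row[f"q{int(q * 100)}"] = float(group["start_offset"].quantile(q))
        rows.append(row)
    return pd.DataFrame(rows)


def tsd_length_distribution(results: Iterable[ReplicateResult]) -> pd.DataFrame:
    """Histogram of predicted interval lengths (end - start) of non-reference
    predictions, per method.  Split-read detectors that resolve breakpoints
    should concentrate at the true TSD length."""
    counts: dict[tuple[str, int], int] = {}
    for res in results:
        for length in res.tsd_lengths:
            key = (res.method, length)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"method": m, "tsd_length": l, "count": c}
        for (m, l), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["method", "tsd_length", "count"])


def tp_overlap_matrix(
    per_method: Mapping[str, Sequence[ReplicateResult]],
    window: int,
    fold_coverage: float | None = None,
) -> pd.DataFrame:
    """Count replicates by the subset of methods that scored a TP (UpSet
    plot input).

    All methods must be scored on identical replicate sets.  Returns one row
    per distinct method subset with its replicate count; the empty subset
    (no method found the insertion) is included.
    """
    methods = sorted(per_method)
    if not methods:
        raise ValueError("no methods supplied")
    rep_sets = {}
    for method in methods:
        results = [
            r
            for r in per_method[method]
            if fold_coverage is None or r.fold_coverage == fold_coverage
        ]
        rep_sets[method] = {r.replicate_id: r for r in results}
    ids = sorted(rep_sets[methods[0]])
    for method in methods[1:]:
        if sorted(rep_sets[method]) != ids:
            raise ValueError("replicate sets differ across methods")
    subset_counts: dict[tuple[str, ...], int] = {}
    for rid in ids:
        members = tuple(
            m for m in methods if rep_sets[m][rid].tp.get(window, 0) == 1
        )
        subset_counts[members] = subset_counts.get(members, 0) + 1
    rows = [
        {"methods": "&".join(subset) if subset else "(none)",
         "degree": len(subset), "count": count}
        for subset, count in sorted(subset_counts.items())
    ]
    return pd.DataFrame(rows, columns=["methods", "degree", "count"])
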