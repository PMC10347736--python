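"""Independent brute-force reference implementations used as test oracles.

Deliberately written without reusing any tebench scoring code: every
prediction is checked pairwise against the truth and against every other
qualifying prediction, O(n^2), so the fast path can be validated against
exhaustive enumeration.
"""

from __future__ import annotations


def brute_force_counts(predictions, truth, window, strand_mode="lenient"):
    """Return (TP, FP, FN, tp_prediction_or_None) for one window size."""
    nonref = []
    for p in predictions:
        if p.category == "non-reference":
            nonref.append(p)

    truth_start = truth.insert_pos
    truth_end = truth.insert_pos + truth.tsd_len

    qualifying = []
    for p in nonref:
        if p.chrom != truth.chrom:
            continue
        if p.family != truth.family:
            continue
        if strand_mode == "lenient":
            strand_ok = p.strand == truth.strand or p.strand == "."
        else:
            strand_ok = p.strand == truth.strand
        if not strand_ok:
            continue
        if abs(p.start - truth_start) > window:
            continue
        if abs(p.end - truth_end) > window:
            continue
        qualifying.append(p)

    if not qualifying:
        return 0, len(nonref), 1, None

    # exhaustive pairwise selection of the single TP: closest |start offset|,
    # ties toward the smaller start coordinate
    best = qualifying[0]
    for cand in qualifying[1:]:
        d_best = abs(best.start - truth_start)
        d_cand = abs(cand.start - truth_start)
        if d_cand < d_best or (d_cand == d_best and cand.start < best.start):
            best = cand
    return 1, len(nonref) - 1, 0, best


def brute_force_upset(per_method_tp, method_names):
    """Enumerate method-subset membership counts from {method: {rep: tp}}."""
    counts = {}
    rep_ids = sorted(next(iter(per_method_tp.values())).keys())
    for rid in rep_ids:
        members = tuple(m for m in method_names if per_method_tp[m][rid])
        counts[members] = counts.get(members, 0) + 1
    return counts
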