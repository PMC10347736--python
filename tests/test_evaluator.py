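import numpy as np
import pandas as pd
import pytest

from tebench.evaluator import (
    DEFAULT_WINDOWS,
    classify_replicate,
    positional_accuracy,
    precision_recall,
    tp_overlap_matrix,
    tsd_length_distribution,
)
from tebench.formats_io import PredictionRecord
from tebench.synthetic_insertion import InsertionTruth

from .reference_impl import brute_force_counts, brute_force_upset

TRUTH = InsertionTruth("chrI", 100, 5, "Ty1", "Ty1", "+", replicate_id=0)


def _pred(chrom="chrI", start=100, end=105, family="Ty1", category="non-reference",
          strand="+", method="m"):
    return PredictionRecord(chrom, start, end, family, category, strand, method)


# ---------------------------------------------------------------------------
# classify_replicate
# ---------------------------------------------------------------------------


def test_exact_match_is_tp_at_window_zero():
    res = classify_replicate([_pred()], TRUTH)
    for n in DEFAULT_WINDOWS:
        assert (res.tp[n], res.fp[n], res.fn[n]) == (1, 0, 0)


def test_one_tp_rule_other_predictions_are_fp():
    preds = [
        _pred(),                                   # exact -> TP
        _pred(start=102, end=107),                 # qualifies at N=5, not TP
        _pred(chrom="chrV", start=500, end=505, family="Ty2"),  # FP
    ]
    res = classify_replicate(preds, TRUTH, chrom_names=["chrI", "chrV"])
    assert (res.tp[5], res.fp[5], res.fn[5]) == (1, 2, 0)
    assert (res.tp[0], res.fp[0], res.fn[0]) == (1, 2, 0)


def test_empty_predictions_are_fn_everywhere():
    res = classify_replicate([], TRUTH)
    for n in DEFAULT_WINDOWS:
        assert (res.tp[n], res.fp[n], res.fn[n]) == (0, 0, 1)


def test_window_zero_requires_identical_coordinates():
    res = classify_replicate([_pred(start=101, end=106)], TRUTH)
    assert res.tp[0] == 0 and res.fn[0] == 1
    assert res.tp[5] == 1


def test_wrong_family_never_tp():
    res = classify_replicate([_pred(family="Ty2")], TRUTH)
    assert all(res.tp[n] == 0 for n in DEFAULT_WINDOWS)
    assert res.fp[500] == 1


def test_strand_mode_lenient_vs_strict():
    dot = [_pred(strand=".")]
    assert classify_replicate(dot, TRUTH, strand_mode="lenient").tp[0] == 1
    assert classify_replicate(dot, TRUTH, strand_mode="strict").tp[0] == 0
    minus = [_pred(strand="-")]
    assert classify_replicate(minus, TRUTH, strand_mode="lenient").tp[0] == 0


def test_reference_predictions_counted_but_never_scored():
    preds = [_pred(category="reference"), _pred()]
    res = classify_replicate(preds, TRUTH)
    assert res.n_reference == 1 and res.n_nonreference == 1
    assert (res.tp[0], res.fp[0]) == (1, 0)


def test_unknown_chromosome_rejected():
    with pytest.raises(ValueError, match="unknown chromosome"):
        classify_replicate([_pred(chrom="chrZ")], TRUTH, chrom_names=["chrI"])


def test_tp_tie_break_closest_start_then_smaller():
    preds = [_pred(start=103, end=108), _pred(start=97, end=102)]
    res = classify_replicate(preds, TRUTH)
    # both |ds| = 3: smaller start (97) wins
    assert res.offsets[5] == (-3, -3)


def _random_instance(rng):
    truth = InsertionTruth(
        chrom=rng.choice(["chrA", "chrB"]),
        insert_pos=int(rng.integers(500, 1500)),
        tsd_len=int(rng.integers(0, 8)),
        te_name="T",
        family=str(rng.choice(["Ty1", "Ty2"])),
        strand=str(rng.choice(["+", "-"])),
        replicate_id=0,
    )
    preds = []
    for _ in range(rng.integers(0, 51)):
        near = rng.random() < 0.6
        if near:
            start = truth.insert_pos + int(rng.integers(-550, 551))
        else:
            start = int(rng.integers(0, 3000))
        length = int(rng.integers(1, 12))
        preds.append(
            PredictionRecord(
                chrom=str(rng.choice(["chrA", "chrB"])),
                start=max(0, start),
                end=max(0, start) + length,
                family=str(rng.choice(["Ty1", "Ty2"])),
                category=str(rng.choice(["non-reference", "non-reference", "reference"])),
                strand=str(rng.choice(["+", "-", "."])),
                method="m",
            )
        )
    return truth, preds


@pytest.mark.parametrize("strand_mode", ["lenient", "strict"])
def test_oracle_equivalence_on_random_instances(strand_mode):
    """classify_replicate agrees with the exhaustive O(n^2) reference
    implementation on TP/FP/FN at all five windows, 300 random instances."""
    rng = np.random.default_rng(2024)
    for _ in range(300):
        truth, preds = _random_instance(rng)
        res = classify_replicate(preds, truth, strand_mode=strand_mode)
        for n in DEFAULT_WINDOWS:
            tp, fp, fn, best = brute_force_counts(preds, truth, n, strand_mode)
            assert (res.tp[n], res.fp[n], res.fn[n]) == (tp, fp, fn)
            if best is not None:
                assert res.offsets[n] == (
                    best.start - truth.insert_pos,
                    best.end - (truth.insert_pos + truth.tsd_len),
                )


def test_conservation_and_monotonicity_on_random_instances():
    """TP + FN = 1 and TP + FP = n_nonreference per window; recall is
    non-decreasing over nested windows."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        truth, preds = _random_instance(rng)
        res = classify_replicate(preds, truth)
        tps = []
        for n in sorted(DEFAULT_WINDOWS):
            assert res.tp[n] + res.fn[n] == 1
            assert res.tp[n] + res.fp[n] == res.n_nonreference
            tps.append(res.tp[n])
        assert tps == sorted(tps)  # TP non-decreasing with window size


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _result(method, cov, rep, tp_by_window, n_nonref, n_ref=0):
    from tebench.evaluator import ReplicateResult

    res = ReplicateResult(method=method, fold_coverage=cov, replicate_id=rep,
                          n_reference=n_ref, n_nonreference=n_nonref)
    for n, tp in tp_by_window.items():
        res.tp[n] = tp
        res.fn[n] = 1 - tp
        res.fp[n] = n_nonref - tp
    return res


def test_precision_recall_formulae():
    results = [
        _result("m", 50, 0, {0: 1}, n_nonref=3),   # TP 1 FP 2
    ]
    frame = precision_recall(results)
    row = frame.iloc[0]
    assert row["recall"] == 1.0
    assert row["precision"] == pytest.approx(1 / 3)


def test_precision_missing_when_no_calls():
    results = [_result("m", 50, r, {0: 0}, n_nonref=0) for r in range(5)]
    frame = precision_recall(results)
    row = frame.iloc[0]
    assert row["recall"] == 0.0
    assert np.isnan(row["precision"])
    assert row["FN"] == 5


def test_precision_recall_sums_before_ratio():
    results = [
        _result("m", 50, r, {0: 1 if r < 9 else 0}, n_nonref=1 if r < 9 else 1)
        for r in range(10)
    ]
    # replicate 9: one wrong call (FP), no TP
    frame = precision_recall(results)
    row = frame.iloc[0]
    assert row["recall"] == pytest.approx(0.9)
    assert row["precision"] == pytest.approx(0.9)


def test_precision_recall_empty_input_rejected():
    with pytest.raises(ValueError):
        precision_recall([])


def test_positional_accuracy_degenerate_at_zero_for_exact_tps():
    res = classify_replicate([_pred()], TRUTH, method="m", fold_coverage=50)
    frame = positional_accuracy([res])
    assert frame["start_offset"].tolist() == [0]
    assert frame["end_offset"].tolist() == [0]


def test_tsd_length_distribution_counts():
    preds = [_pred(), _pred(start=200, end=205), _pred(start=300, end=301)]
    res = classify_replicate(preds, TRUTH, method="m")
    frame = tsd_length_distribution([res])
    counts = dict(zip(frame["tsd_length"], frame["count"]))
    assert counts == {5: 2, 1: 1}


# ---------------------------------------------------------------------------
# UpSet overlaps
# ---------------------------------------------------------------------------


def test_tp_overlap_simple_cases():
    a1 = _result("A", 50, 0, {100: 1}, 1)
    b1 = _result("B", 50, 0, {100: 1}, 1)
    frame = tp_overlap_matrix({"A": [a1], "B": [b1]}, window=100)
    assert frame.loc[frame["methods"] == "A&B", "count"].item() == 1

    b0 = _result("B", 50, 0, {100: 0}, 0)
    frame = tp_overlap_matrix({"A": [a1], "B": [b0]}, window=100)
    assert frame.loc[frame["methods"] == "A", "count"].item() == 1


def test_tp_overlap_matches_enumeration_oracle():
    rng = np.random.default_rng(13)
    methods = ["A", "B", "C"]
    per_method = {}
    tp_by = {}
    for m in methods:
        tp_by[m] = {r: int(rng.integers(0, 2)) for r in range(4)}
        per_method[m] = [
            _result(m, 50, r, {100: tp_by[m][r]}, tp_by[m][r]) for r in range(4)
        ]
    frame = tp_overlap_matrix(per_method, window=100)
    expected = brute_force_upset(tp_by, methods)
    got = {
        tuple(r["methods"].split("&")) if r["methods"] != "(none)" else (): r["count"]
        for _, r in frame.iterrows()
    }
    assert got == expected


def test_tp_overlap_requires_identical_replicate_sets():
    a = [_result("A", 50, 0, {100: 1}, 1)]
    b = [_result("B", 50, 1, {100: 1}, 1)]
    with pytest.raises(ValueError, match="replicate sets differ"):
        tp_overlap_matrix({"A": a, "B": b}, window=100)
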