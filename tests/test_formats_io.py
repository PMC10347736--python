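import numpy as np
import pytest

from tebench import formats_io as fio


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_fasta_case_normalization(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chrI\nacgt\n")
    seqs = fio.read_fasta(p)
    assert seqs.names() == ["chrI"]
    assert seqs["chrI"] == "ACGT"


def test_fasta_duplicate_names_rejected(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">x\nACGT\n>x\nTTTT\n")
    with pytest.raises(fio.FormatError, match="duplicate"):
        fio.read_fasta(p)


def test_fasta_bad_alphabet_rejected(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">x\nACGU\n")
    with pytest.raises(fio.FormatError, match="non-nucleotide"):
        fio.read_fasta(p)


def test_empty_fasta_warns_and_yields_empty_set(tmp_path, caplog):
    p = tmp_path / "empty.fa"
    p.write_text("")
    with caplog.at_level("WARNING", logger="tebench"):
        seqs = fio.read_fasta(p)
    assert len(seqs) == 0
    assert any("no records" in rec.message for rec in caplog.records)


def test_fasta_round_trip(tmp_path):
    original = fio.SequenceSet({"chrI": "ACGTN" * 40, "chrII": "TTTTACGT"})
    path = tmp_path / "rt.fa"
    fio.write_fasta(original, path)
    assert fio.read_fasta(path) == original


# ---------------------------------------------------------------------------
# Prediction BED dialect
# ---------------------------------------------------------------------------


def test_prediction_bed_parse(tmp_path):
    p = tmp_path / "pred.bed"
    p.write_text("chrI\t100\t105\tTy1|non-reference\t0\t+\n")
    recs = fio.read_predictions_bed(p, "relocate2")
    assert len(recs) == 1
    r = recs[0]
    assert (r.chrom, r.start, r.end) == ("chrI", 100, 105)
    assert r.family == "Ty1"
    assert r.category == "non-reference"
    assert r.strand == "+"
    assert r.method == "relocate2"


def test_prediction_bed_extra_name_fields_ignored(tmp_path):
    p = tmp_path / "pred.bed"
    p.write_text("chrI\t100\t105\tTy1|reference|extra|stuff\t0\t-\n")
    recs = fio.read_predictions_bed(p, "m")
    assert recs[0].category == "reference"


def test_prediction_bed_empty_interval_rejected(tmp_path):
    p = tmp_path / "pred.bed"
    p.write_text("chrI\t5\t5\tTy1|non-reference\t0\t+\n")
    with pytest.raises(fio.FormatError, match="pred.bed:1"):
        fio.read_predictions_bed(p, "m")


def test_prediction_bed_missing_category_rejected(tmp_path):
    p = tmp_path / "pred.bed"
    p.write_text("chrI\t10\t15\tTy1\t0\t+\n")
    with pytest.raises(fio.FormatError, match="non-reference"):
        fio.read_predictions_bed(p, "m")


def test_prediction_bed_round_trip(tmp_path):
    path = tmp_path / "rt.bed"
    path.write_text(
        "chrI\t100\t105\tTy1|non-reference\t0\t+\n"
        "chrII\t7\t400\tTy2|reference\t0\t-\n"
    )
    recs = fio.read_predictions_bed(path, "m")
    out = tmp_path / "out.bed"
    fio.write_predictions_bed(recs, out)
    assert out.read_text() == path.read_text()


# ---------------------------------------------------------------------------
# GFF coordinate convention
# ---------------------------------------------------------------------------


def test_gff_converts_to_zero_based_half_open(tmp_path):
    p = tmp_path / "x.gff"
    p.write_text("##gff-version 3\nchrI\tsrc\tTE\t101\t200\t.\t+\t.\tID=TyA\n")
    ivs = fio.read_gff(p)
    assert (ivs[0].start, ivs[0].end) == (100, 200)
    assert ivs[0].label == "TyA"


def test_gff_round_trip_is_involutive(tmp_path):
    ivs = [fio.GenomicInterval("chr1", 10, 50, strand="+", label="a"),
           fio.GenomicInterval("chr2", 0, 7, strand="-", label="b")]
    path = tmp_path / "rt.gff"
    fio.write_gff(ivs, path)
    assert fio.read_gff(path) == ivs


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def test_vcf_pos_is_one_based(tmp_path):
    ref = fio.SequenceSet({"chrI": "A" * 200})
    rec = fio.PredictionRecord("chrI", 100, 105, "Ty1", "non-reference", "+", "m",
                               tsd_len=5)
    out = tmp_path / "x.vcf"
    fio.write_vcf([rec], ref, out)
    data = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert len(data) == 1
    fields = data[0].split("\t")
    assert fields[0] == "chrI"
    assert fields[1] == "101"
    assert "<INS:ME:Ty1>" in fields[4]
    assert "END=105" in fields[7] and "TSDLEN=5" in fields[7]


def test_vcf_empty_records_gives_header_only(tmp_path):
    ref = fio.SequenceSet({"chrI": "ACGT"})
    out = tmp_path / "x.vcf"
    fio.write_vcf([], ref, out)
    lines = out.read_text().splitlines()
    assert all(l.startswith("#") for l in lines)
    assert lines[0] == "##fileformat=VCFv4.2"


def test_vcf_parses_with_independent_reader(tmp_path):
    """The emitted VCF round-trips through an independent VCF parser."""
    cyvcf2 = pytest.importorskip("cyvcf2")
    ref = fio.SequenceSet({"chrI": "ACGT" * 100})
    recs = [
        fio.PredictionRecord("chrI", 10, 15, "Ty1", "non-reference", "+", "m",
                             tsd_len=5),
        fio.PredictionRecord("chrI", 50, 55, "Ty2", "non-reference", "-", "m"),
    ]
    path = tmp_path / "x.vcf"
    fio.write_vcf(recs, ref, path)
    parsed = list(cyvcf2.VCF(str(path)))
    assert [v.POS for v in parsed] == [11, 51]
    assert parsed[0].ALT == ["<INS:ME:Ty1>"]
    assert parsed[0].INFO["END"] == 15
    assert parsed[0].INFO["TSDLEN"] == 5


def test_vcf_unknown_chrom_rejected(tmp_path):
    ref = fio.SequenceSet({"chrI": "ACGT"})
    rec = fio.PredictionRecord("chrX", 1, 2, "Ty1", "non-reference", "+", "m")
    with pytest.raises(fio.FormatError, match="chrX"):
        fio.write_vcf([rec], ref, tmp_path / "x.vcf")


# ---------------------------------------------------------------------------
# fixedStep WIG
# ---------------------------------------------------------------------------


def test_wig_fixed_step_basic(tmp_path):
    p = tmp_path / "x.wig"
    p.write_text("fixedStep chrom=chrI start=1 step=1\n1.0\n2.0\n3.0\n")
    track = fio.read_wig(p)
    np.testing.assert_allclose(track.values["chrI"], [1.0, 2.0, 3.0])


def test_wig_two_blocks_zero_filled_gap(tmp_path):
    # positionwise oracle: value v_k sits at 0-based position (start-1) + k*step
    p = tmp_path / "x.wig"
    p.write_text(
        "fixedStep chrom=chrI start=1 step=1\n5\n5\n"
        "fixedStep chrom=chrI start=6 step=1\n7\n"
    )
    track = fio.read_wig(p)
    expected = np.zeros(6)
    expected[0] = expected[1] = 5.0
    expected[5] = 7.0
    np.testing.assert_allclose(track.values["chrI"], expected)


def test_wig_step_and_start_offsets(tmp_path):
    p = tmp_path / "x.wig"
    p.write_text("fixedStep chrom=chrI start=3 step=5\n1\n2\n")
    track = fio.read_wig(p)
    vec = track.values["chrI"]
    # values at 0-based positions 2 and 7; all else zero
    assert vec[2] == 1.0 and vec[7] == 2.0
    assert vec[:2].sum() == 0 and vec[3:7].sum() == 0


def test_wig_variable_step_rejected(tmp_path):
    p = tmp_path / "x.wig"
    p.write_text("variableStep chrom=chrI\n1\t5\n")
    with pytest.raises(fio.FormatError, match="variableStep"):
        fio.read_wig(p)


def test_wig_negative_step_rejected(tmp_path):
    p = tmp_path / "x.wig"
    p.write_text("fixedStep chrom=chrI start=1 step=-1\n1\n")
    with pytest.raises(fio.FormatError, match="step"):
        fio.read_wig(p)


def test_wig_round_trip(tmp_path):
    track = fio.SignalTrack(values={"chr1": np.array([0.0, 1.5, 2.0, 0.5])})
    path = tmp_path / "rt.wig"
    fio.write_wig(track, path)
    back = fio.read_wig(path)
    np.testing.assert_allclose(back.values["chr1"], track.values["chr1"])


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


def test_taxonomy_round_trip(tmp_path):
    tax = {"TY1": "Ty1", "TY1-LTR": "Ty1", "TY2": "Ty2"}
    path = tmp_path / "tax.tsv"
    fio.write_taxonomy(tax, path)
    assert fio.read_taxonomy(path) == tax


def test_taxonomy_malformed_line_rejected(tmp_path):
    p = tmp_path / "tax.tsv"
    p.write_text("TY1\n")
    with pytest.raises(fio.FormatError, match="tax.tsv:1"):
        fio.read_taxonomy(p)
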