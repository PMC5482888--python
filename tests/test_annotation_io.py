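"""Annotation parsing, circular coordinate arithmetic and validation."""

import pytest

from mitocomp import (
    GeneFeature, MitogenomeRecord, feature_length, intergenic_spacer,
    read_feature_table, read_genbank, strand_counts, validate_annotation,
    write_feature_table, write_genbank,
)
from mitocomp.annotation_io import AnnotationFormatError
from mitocomp.vocab import UnknownGeneError, canonical_name


@pytest.mark.parametrize("gene,size", [
    ("cox1", 1535), ("rrnL", 1336), ("rrnS", 832), ("CR", 684),
    ("nad5", 1731), ("atp8", 159), ("trnV", 73),
])
def test_feature_lengths_match_published_sizes(reference_record, gene, size):
    f = reference_record.feature(gene)
    assert feature_length(f, reference_record.genome_length) == size


def test_genome_length_is_max_end_coordinate(reference_record):
    assert reference_record.genome_length == 15_706
    assert max(f.end for f in reference_record.features) == 15_706
    assert len(reference_record.features) == 38


def test_wrapped_feature_length_matches_position_enumeration():
    # feature spanning the origin of a 15,706 bp circle: 15,700..5
    f = GeneFeature(name="CR", gene_class="CR", orientation=None,
                    start=15_700, end=5)
    positions = []
    pos = 15_700
    while pos != 5:
        positions.append(pos)
        pos = pos % 15_706 + 1
    positions.append(5)
    assert feature_length(f, 15_706) == len(positions) == 12


def test_single_base_feature_has_length_one():
    f = GeneFeature(name="CR", gene_class="CR", orientation=None,
                    start=5, end=5)
    assert feature_length(f, 100) == 1


@pytest.mark.parametrize("prev,nxt,expected", [
    ("atp8", "atp6", -7),       # published overlap
    ("trnQ", "trnI", 70),       # pseudogene-remnant gap: 14,270..14,339
    ("cox1", "trnL2", 0),       # abutting
    ("trnY", "cox1", 0),        # wrap pair closes the circle exactly
])
def test_intergenic_spacers_recomputed_from_coordinates(
        reference_record, prev, nxt, expected):
    gl = reference_record.genome_length
    assert intergenic_spacer(reference_record.feature(prev),
                             reference_record.feature(nxt), gl) == expected


def test_spacer_of_feature_with_itself_is_negative_length(reference_record):
    f = reference_record.feature("cox1")
    gl = reference_record.genome_length
    assert intergenic_spacer(f, f, gl) == -feature_length(f, gl)


def test_strand_counts_and_flip_symmetry(reference_record):
    assert strand_counts(reference_record) == (23, 14)
    flipped = MitogenomeRecord(
        accession="flip", genome_length=reference_record.genome_length,
        features=[
            GeneFeature(name=f.name, gene_class=f.gene_class,
                        orientation={"J": "N", "N": "J", None: None}[
                            f.orientation],
                        start=f.start, end=f.end, anticodon=f.anticodon,
                        start_codon=f.start_codon, stop_codon=f.stop_codon)
            for f in reference_record.features])
    assert strand_counts(flipped) == (14, 23)


def test_circular_closure_on_annotations(reference_record, synthetic_record):
    # features sorted around the circle tile it: sizes + spacers = length
    for rec in (reference_record, synthetic_record):
        feats = sorted(rec.features, key=lambda f: f.start)
        total = sum(feature_length(f, rec.genome_length) for f in feats)
        total += sum(intergenic_spacer(a, b, rec.genome_length)
                     for a, b in zip(feats, feats[1:] + feats[:1]))
        assert total == rec.genome_length


def test_feature_table_round_trip(tmp_path, reference_record):
    path = tmp_path / "ref.tsv"
    write_feature_table(reference_record, path)
    back = read_feature_table(path)
    assert back.features == reference_record.features
    assert back.genome_length == reference_record.genome_length


def test_genbank_round_trip_preserves_generated_record(
        tmp_path, synthetic_record):
    path = tmp_path / "syn.gb"
    write_genbank(synthetic_record, path)
    back = read_genbank(path)
    assert back.features == synthetic_record.features
    assert back.sequence == synthetic_record.sequence
    assert back.genome_length == synthetic_record.genome_length


def test_feature_table_tolerates_thousands_separators(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "gene\tclass\torientation\tstart\tend\tanticodon\t"
        "start_codon\tstop_codon\n"
        "rrnL\trRNA\tN\t11,277\t12,612\t.\t.\t.\n")
    rec = read_feature_table(path)
    assert (rec.features[0].start, rec.features[0].end) == (11_277, 12_612)


@pytest.mark.parametrize("row,exc,match", [
    ("cox1\tPCG\tJ\tabc\t10\t.\t.\t.", AnnotationFormatError, "row 3"),
    ("frobnitz\tPCG\tJ\t1\t10\t.\t.\t.", UnknownGeneError, "accepted symbols"),
], ids=["bad-coordinate", "unknown-gene"])
def test_malformed_rows_raise_informative_errors(tmp_path, row, exc, match):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "#genome_length=100\n"
        "gene\tclass\torientation\tstart\tend\tanticodon\t"
        "start_codon\tstop_codon\n" + row + "\n")
    with pytest.raises(exc, match=match):
        read_feature_table(path)


def test_header_only_table_is_an_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("gene\tclass\torientation\tstart\tend\tanticodon\t"
                    "start_codon\tstop_codon\n")
    with pytest.raises(AnnotationFormatError, match="no features"):
        read_feature_table(path)


def test_validation_flags_large_spacer_but_no_errors(reference_record):
    findings = validate_annotation(reference_record)
    assert not [f for f in findings if f.level == "error"]
    gap_warnings = [f for f in findings
                    if "trnQ" in f.message and "trnI" in f.message]
    assert gap_warnings and "70" in gap_warnings[0].message


def test_validation_reports_missing_gene_and_bad_coordinates(
        reference_record):
    feats = [f for f in reference_record.features if f.name != "trnH"]
    rec = MitogenomeRecord(accession="x", genome_length=15_706,
                           features=feats)
    assert any(f.level == "warning" and "trnH" in f.message
               for f in validate_annotation(rec))
    bad = MitogenomeRecord(
        accession="y", genome_length=100,
        features=[GeneFeature(name="cox1", gene_class="PCG",
                              orientation="J", start=1, end=500)])
    assert any(f.level == "error" for f in validate_annotation(bad))


@pytest.mark.parametrize("alias,expected", [
    ("COX1", "cox1"), ("nd4l", "nad4L"), ("CYTB", "cob"),
    ("tRNA-Ser(AGN)", "trnS1"), ("tRNA-Leu(UUR)", "trnL2"),
    ("D-loop", "CR"), ("16S", "rrnL"), ("tRNA-His", "trnH"),
])
def test_gene_name_aliases(alias, expected):
    assert canonical_name(alias) == expected
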