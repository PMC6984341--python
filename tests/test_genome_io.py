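"""Circular coordinate handling and annotated-genome I/O."""

import pytest

from mitochar import (
    FeatureTable,
    GeneFeature,
    MitoGenome,
    extract_feature,
    nd5_joined,
    read_feature_tsv,
    read_genbank,
    write_genbank,
)
from mitochar.errors import FeatureError, GenomeParseError
from mitochar.genome_io import standardize_name, write_feature_tsv
from mitochar import presets

TOY = MitoGenome(sequence="ACGTACGT", accession="TOY")


@pytest.mark.parametrize(
    "segments,expected",
    [
        (((7, 10),), "GTAC"),          # wrap through the origin
        (((1, 8),), "ACGTACGT"),       # full circle
        (((1, 3), (6, 8)), "ACGCGT"),  # two segments joined in order
        (((8, 9),), "TA"),             # wrap starting at the last base
    ],
)
def test_extract_feature_wraps_and_joins(segments, expected):
    feat = GeneFeature(name="COI", ftype="PCG", segments=segments)
    assert extract_feature(TOY, feat) == expected


def test_extract_feature_reverse_complements_l_strand():
    feat = GeneFeature(name="COI", ftype="PCG", strand="L", segments=((1, 4),))
    assert extract_feature(TOY, feat) == "ACGT"  # revcomp of ACGT is ACGT
    feat2 = GeneFeature(name="ND1", ftype="PCG", strand="L", segments=((2, 4),))
    assert extract_feature(TOY, feat2) == "ACG"  # revcomp of CGT


def test_extraction_length_law(genome, ftable):
    for feat in ftable:
        assert len(extract_feature(genome, feat)) == feat.span_length


def test_preset_feature_sizes_match_table(genome, ftable):
    for gene, size in presets.GENE_SIZES.items():
        assert len(extract_feature(genome, ftable.get(gene))) == size


def test_nd5_joined_skips_intron(genome, ftable):
    joined = nd5_joined(ftable)
    seq = extract_feature(genome, joined)
    assert len(seq) == 711 + 1104
    five = extract_feature(genome, ftable.get("ND5-5prime"))
    three = extract_feature(genome, ftable.get("ND5-3prime"))
    assert seq == five + three


def test_genome_rejects_bad_alphabet():
    with pytest.raises(GenomeParseError):
        MitoGenome(sequence="ACGTX")


def test_feature_validation():
    with pytest.raises(FeatureError):
        GeneFeature(name="COI", ftype="PCG", segments=())
    with pytest.raises(FeatureError):
        GeneFeature(name="COI", ftype="PCG", segments=((0, 10),))
    with pytest.raises(FeatureError):
        GeneFeature(name="COI", ftype="gene", segments=((1, 10),))
    with pytest.raises(FeatureError):
        FeatureTable(genome_ref="x", features=[
            GeneFeature(name="COI", ftype="PCG", segments=((1, 9),)),
            GeneFeature(name="COI", ftype="PCG", segments=((20, 28),)),
        ])


def test_genbank_roundtrip_identity(genome, ftable, tmp_path):
    path = tmp_path / "syn.gb"
    write_genbank(genome, ftable, path)
    genome2, ftable2 = read_genbank(path)
    assert genome2.sequence == genome.sequence
    assert genome2.accession == genome.accession
    assert genome2.organism == genome.organism
    assert genome2.is_circular
    assert [(f.name, f.ftype, f.strand, f.segments) for f in ftable] == \
           [(f.name, f.ftype, f.strand, f.segments) for f in ftable2]


def test_genbank_roundtrip_wrapping_feature(tmp_path):
    seq = "ATGAAATTTTAA" * 6  # 72 bp
    genome = MitoGenome(sequence=seq, accession="WRAP")
    table = FeatureTable(genome_ref="WRAP", features=[
        GeneFeature(name="tRNA-Met", ftype="tRNA", segments=((65, 76),)),
    ])
    path = tmp_path / "wrap.gb"
    write_genbank(genome, table, path)
    _, table2 = read_genbank(path)
    assert table2.get("tRNA-Met").segments == ((65, 76),)


def test_read_genbank_unknown_gene_skipped_with_warning(genome, ftable,
                                                        tmp_path, caplog):
    path = tmp_path / "unk.gb"
    write_genbank(genome, ftable, path)
    text = path.read_text().replace('/gene="COI"', '/gene="mystery7"')
    path.write_text(text)
    with caplog.at_level("WARNING"):
        _, table2 = read_genbank(path)
    assert "mystery7" in caplog.text
    assert len(table2) == len(ftable) - 1


def test_read_genbank_no_features_warns(tmp_path, caplog):
    genome = MitoGenome(sequence="ACGT" * 30, accession="EMPTY")
    path = tmp_path / "empty.gb"
    write_genbank(genome, FeatureTable(genome_ref="EMPTY"), path)
    with caplog.at_level("WARNING"):
        genome2, table2 = read_genbank(path)
    assert genome2.sequence == genome.sequence
    assert len(table2) == 0
    assert "no annotated gene features" in caplog.text


def test_read_genbank_missing_origin_errors(tmp_path):
    path = tmp_path / "noorigin.gb"
    path.write_text(
        "LOCUS       X 120 bp DNA circular INV 01-JAN-2020\n"
        "DEFINITION  test.\n"
        "FEATURES             Location/Qualifiers\n"
        "ORIGIN\n//\n"
    )
    with pytest.raises(GenomeParseError):
        read_genbank(path)


def test_feature_tsv_parsing(tmp_path):
    genome = MitoGenome(sequence="A" * 18000, accession="BIG")
    path = tmp_path / "feat.tsv"
    path.write_text(
        "name\tftype\tstrand\tsegments\n"
        "COI\tPCG\tH\t100..1692\n"
        "ND5\tPCG\tH\t700..1410,10300..11403\n"
    )
    table = read_feature_tsv(genome, path)
    assert table.get("COI").span_length == 1593
    nd5 = table.get("ND5")
    assert len(nd5.segments) == 2
    assert nd5.span_length == 711 + 1104 == 1815


def test_feature_tsv_roundtrip(genome, ftable, tmp_path):
    path = tmp_path / "rt.tsv"
    write_feature_tsv(ftable, path)
    table2 = read_feature_tsv(genome, path)
    assert [(f.name, f.ftype, f.strand, f.segments) for f in ftable] == \
           [(f.name, f.ftype, f.strand, f.segments) for f in table2]


def test_feature_tsv_errors_name_line(tmp_path):
    genome = MitoGenome(sequence="A" * 100, accession="S")
    bad_coord = tmp_path / "bad1.tsv"
    bad_coord.write_text("COI\tPCG\tH\t10..300\n")
    with pytest.raises(FeatureError, match="bad1.tsv:1"):
        read_feature_tsv(genome, bad_coord)
    bad_seg = tmp_path / "bad2.tsv"
    bad_seg.write_text("COI\tPCG\tH\t10--20\n")
    with pytest.raises(FeatureError, match="bad2.tsv:1"):
        read_feature_tsv(genome, bad_seg)


def test_feature_tsv_empty_file(tmp_path):
    genome = MitoGenome(sequence="A" * 100, accession="S")
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert len(read_feature_tsv(genome, path)) == 0


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("nad5", "ND5"), ("cox1", "COI"), ("COX3", "COIII"), ("cob", "CYTB"),
        ("Cyt b", "CYTB"), ("trnM", "tRNA-Met"), ("12S ribosomal RNA", "12S rRNA"),
        ("rrnL", "16S rRNA"), ("ND5-5prime", "ND5-5prime"), ("ND5 5'", "ND5-5prime"),
        ("ATPase6", "ATP6"), ("mystery", None),
    ],
)
def test_standardize_name(raw, expected):
    assert standardize_name(raw) == expected
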