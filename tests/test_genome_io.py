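"""Parsing, name normalization and circular-coordinate primitives."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from plastocomp.genome_io import (circular_distance, extract_cds_and_upstream,
                                  normalize_gene_name, read_genbank,
                                  reflect_genome, rotate_genome, revcomp,
                                  write_genbank)


@pytest.mark.parametrize(
    ("raw", "expected"),
    [
        ("ATPI", "atpI"),
        ("atpI", "atpI"),
        ("PSBA", "psbA"),
        ("rpl12", "rpl12"),
        ("RPOC1", "rpoC1"),
        ("tufa", "tufA"),
        ("ycf3", "ycf3"),
        ("tRNA-Leu(gag)", "trnL(GAG)"),
        ("tRNA-Thr(ggt)", "trnT(GGU)"),
        ("trnL-GAG", "trnL(GAG)"),
        ("trnS(gga)", "trnS(GGA)"),
        ("16S ribosomal RNA", "rrs"),
        ("23S ribosomal RNA", "rrl"),
        ("rrn5", "rrf"),
        ("hypothetical chloroplast RF21", "hypothetical chloroplast RF21"),
    ],
)
def test_normalize_gene_name(raw, expected):
    assert normalize_gene_name(raw) == expected


def test_normalize_is_idempotent():
    for raw in ("ATPI", "tRNA-Leu(gag)", "16S ribosomal RNA", "rpoC1"):
        once = normalize_gene_name(raw)
        assert normalize_gene_name(once) == once


def test_trna_anticodon_identity_is_preserved():
    # trnL(GAG) and trnL(UAA) are different genes
    assert normalize_gene_name("trnL-GAG") != normalize_gene_name("trnL-UAA")


@pytest.mark.parametrize(
    ("a", "b", "L", "expected"),
    [(0, 10, 100, 10), (95, 5, 100, 10), (42, 42, 100, 0), (0, 50, 100, 50)],
)
def test_circular_distance_examples(a, b, L, expected):
    assert circular_distance(a, b, L) == expected


@given(st.integers(1, 10_000), st.data())
@settings(max_examples=100, derandomize=True)
def test_circular_distance_properties(L, data):
    a = data.draw(st.integers(0, L - 1))
    b = data.draw(st.integers(0, L - 1))
    d = circular_distance(a, b, L)
    assert d == circular_distance(b, a, L)
    assert 0 <= d <= L // 2
    assert circular_distance(a, a, L) == 0


def test_circular_distance_rejects_bad_length():
    with pytest.raises(ValueError):
        circular_distance(0, 1, 0)


def _write_record(path, rec):
    seqio_write(rec, str(path), "genbank")


def test_single_cds_with_enclosing_gene_merges(tmp_path):
    """A CDS and its enclosing gene feature become one protein feature."""
    seq = "A" * 30 + revcomp("ATG" + "GCT" * 8 + "TAA") + "T" * 40
    rec = SeqRecord(Seq(seq), id="mini", name="mini", description="",
                    annotations={"molecule_type": "DNA",
                                 "topology": "circular"})
    loc = SimpleLocation(30, 60, strand=-1)
    rec.features.append(SeqFeature(loc, type="gene",
                                   qualifiers={"gene": ["psbA"]}))
    rec.features.append(SeqFeature(loc, type="CDS",
                                   qualifiers={"gene": ["psbA"]}))
    path = tmp_path / "mini.gb"
    _write_record(path, rec)

    genome = read_genbank(path)
    assert len(genome.features) == 1
    f = genome.features[0]
    assert (f.name, f.gene_type, f.category, f.strand) == \
        ("psbA", "protein", "photosynthesis", -1)
    assert (f.start, f.end) == (30, 60)


def test_origin_spanning_join_resolved_to_wrap(tmp_path):
    seq = "ACGT" * 25  # 100 bp
    rec = SeqRecord(Seq(seq), id="wrap", name="wrap", description="",
                    annotations={"molecule_type": "DNA",
                                 "topology": "circular"})
    loc = CompoundLocation([SimpleLocation(90, 100, strand=1),
                            SimpleLocation(0, 20, strand=1)])
    rec.features.append(SeqFeature(loc, type="CDS",
                                   qualifiers={"gene": ["atpA"]}))
    path = tmp_path / "wrap.gb"
    _write_record(path, rec)

    genome = read_genbank(path)
    f = genome.features[0]
    assert f.wraps and (f.start, f.end) == (90, 20)
    assert f.length(100) == 30


def test_genbank_round_trip(study, tmp_path):
    """write(read(x)) preserves sequence and every feature field."""
    for genome in (study.reference, study.reduced):
        path = tmp_path / f"{genome.id}.gb"
        write_genbank(genome, path)
        back = read_genbank(path)
        assert back.sequence == genome.sequence
        assert [
            (f.name, f.gene_type, f.category, f.strand, f.start, f.end, f.wraps)
            for f in back.features
        ] == [
            (f.name, f.gene_type, f.category, f.strand, f.start, f.end, f.wraps)
            for f in genome.features
        ]


def test_extract_cds_plus_strand_coordinates(study):
    genome = study.reference
    plus = next(f for f in genome.features
                if f.strand == 1 and f.gene_type == "protein" and not f.wraps)
    ext = extract_cds_and_upstream(genome, plus.name, 50)
    assert ext.cds == genome.sequence[plus.start: plus.end]
    assert ext.upstream == genome.sequence[plus.start - 50: plus.start]


def test_extract_cds_minus_strand_is_reverse_complement(study):
    genome = study.reference
    minus = next(f for f in genome.features
                 if f.strand == -1 and f.gene_type == "protein" and not f.wraps)
    ext = extract_cds_and_upstream(genome, minus.name, 50)
    assert ext.cds == revcomp(genome.sequence[minus.start: minus.end])
    assert ext.upstream == revcomp(
        genome.sequence[minus.end: minus.end + 50])
    assert ext.cds.startswith("ATG")


def test_extract_upstream_wraps_origin(study):
    """Upstream extraction through the origin agrees with the same genome
    rotated so the gene sits in the interior."""
    original = study.reference
    gene = next(f for f in original.features
                if f.strand == 1 and f.gene_type == "protein" and not f.wraps)
    # place the gene 10 bp after the origin: its 50 bp upstream window wraps
    genome = rotate_genome(original, gene.start - 10)
    target = next(f for f in genome.features if f.name == gene.name)
    assert target.start == 10
    ext = extract_cds_and_upstream(genome, target.name, 50)
    interior = rotate_genome(genome, len(genome) // 2)
    ext2 = extract_cds_and_upstream(interior, target.name, 50)
    assert ext.cds == ext2.cds
    assert ext.upstream == ext2.upstream


def test_extract_missing_gene_raises(study):
    with pytest.raises(KeyError):
        extract_cds_and_upstream(study.reference, "nadH", 50)


def test_rotation_preserves_feature_lengths(study):
    genome = study.reference
    L = len(genome)
    for offset in (1, 1234, L - 1):
        rotated = rotate_genome(genome, offset)
        assert sorted(f.length(L) for f in rotated.features) == \
            sorted(f.length(L) for f in genome.features)


def test_reflection_is_involutive(study):
    genome = study.reference
    back = reflect_genome(reflect_genome(genome))
    assert back.sequence == genome.sequence
    assert [(f.name, f.start, f.end, f.strand) for f in back.features] == \
        [(f.name, f.start, f.end, f.strand) for f in genome.features]
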