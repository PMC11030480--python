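"""Coordinate mapping, SNV enumeration, annotation I/O and gene selection."""

from __future__ import annotations

import textwrap
import warnings

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snrnascan.gene_model import (
    GeneLocus,
    GenomicVariant,
    OutOfLocusError,
    ReferenceMismatchError,
    enumerate_possible_snvs,
    genomic_region_to_transcript,
    genomic_to_transcript,
    load_annotation,
    reverse_complement,
    select_snrna_genes,
    sequence_identity,
    transcript_to_genomic,
)


# ---------------------------------------------------------------------------
# published variant nomenclature on the minus-strand U4-like locus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "position, ref, alt, expected",
    [
        (120_291_839, "T", "TA", "n.64_65insT"),
        (120_291_839, "T", "TC", "n.64_65insG"),
        (120_291_826, "T", "TA", "n.77_78insT"),
        (120_291_827, "T", "TA", "n.76_77insT"),
        (120_291_835, "G", "GT", "n.68_69insA"),
        (120_291_838, "T", "TA", "n.65_66insT"),
        (120_291_839, "T", "C", "n.65A>G"),
        (120_291_826, "T", "G", "n.78A>C"),
        (120_291_828, "G", "A", "n.76C>T"),
        (120_291_835, "G", "A", "n.69C>T"),
        (120_291_837, "T", "C", "n.67A>G"),
        (120_291_841, "A", "C", "n.63T>G"),
    ],
)
def test_minus_strand_nomenclature(u4_gene, position, ref, alt, expected):
    """Every documented genomic/n. pair for the U4-like locus maps by arithmetic."""
    tv = genomic_to_transcript(u4_gene, GenomicVariant("chr12", position, ref, alt))
    assert tv.n_description == expected


def test_plus_strand_substitution(plus_gene):
    tv = genomic_to_transcript(plus_gene, GenomicVariant("chr1", 105, "A", "G"))
    assert tv.n_description == "n.6A>G"


def test_out_of_locus_and_ref_mismatch(u4_gene):
    with pytest.raises(OutOfLocusError):
        genomic_to_transcript(u4_gene, GenomicVariant("chr12", 120_291_762, "A", "C"))
    with pytest.raises(ReferenceMismatchError):
        # locus has T at this position, not C
        genomic_to_transcript(u4_gene, GenomicVariant("chr12", 120_291_839, "C", "A"))


@pytest.mark.parametrize(
    "g_start, g_end, n_start, n_end",
    [
        (120_291_825, 120_291_842, 62, 79),   # critical region
        (120_291_763, 120_291_903, 1, 141),   # whole gene
        (120_291_839, 120_291_839, 65, 65),   # single base
    ],
)
def test_genomic_region_to_transcript(u4_gene, g_start, g_end, n_start, n_end):
    interval = genomic_region_to_transcript(u4_gene, g_start, g_end)
    assert (interval.n_start, interval.n_end) == (n_start, n_end)


def test_minus_strand_position_identity(u4_gene):
    # n(g) + g = end + 1 everywhere on a minus-strand gene
    for g in range(u4_gene.start, u4_gene.end + 1, 7):
        assert u4_gene.transcript_position(g) + g == u4_gene.end + 1


# ---------------------------------------------------------------------------
# round trip property
# ---------------------------------------------------------------------------

@st.composite
def gene_and_variant(draw):
    length = draw(st.integers(10, 60))
    strand = draw(st.sampled_from("+-"))
    seq = "".join(draw(st.lists(st.sampled_from("ACGT"), min_size=length, max_size=length)))
    start = draw(st.integers(1, 10_000))
    gene = GeneLocus("G", "chrT", strand, start, start + length - 1, seq)
    kind = draw(st.sampled_from(["sub", "ins", "del"]))
    if kind == "sub":
        g = draw(st.integers(gene.start, gene.end))
        ref = gene.plus_strand_base(g)
        alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        return gene, GenomicVariant("chrT", g, ref, alt)
    if kind == "ins":
        g = draw(st.integers(gene.start, gene.end - 1))  # strictly inside
        ref = gene.plus_strand_base(g)
        ins = "".join(draw(st.lists(st.sampled_from("ACGT"), min_size=1, max_size=3)))
        return gene, GenomicVariant("chrT", g, ref, ref + ins)
    g = draw(st.integers(gene.start, gene.end - 1))
    span = draw(st.integers(1, min(3, gene.end - g)))
    ref = "".join(gene.plus_strand_base(p) for p in range(g, g + span + 1))
    return gene, GenomicVariant("chrT", g, ref, ref[0])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(gene_and_variant())
def test_round_trip_transcript_genomic(payload):
    """genomic -> transcript -> genomic is the identity on in-locus variants."""
    gene, variant = payload
    tv = genomic_to_transcript(gene, variant)
    assert transcript_to_genomic(gene, tv) == variant


# ---------------------------------------------------------------------------
# possible SNVs and identity
# ---------------------------------------------------------------------------

def test_enumerate_possible_snvs_counts(u4_gene):
    assert len(enumerate_possible_snvs(u4_gene, 120_291_825, 120_291_842)) == 54
    whole = enumerate_possible_snvs(u4_gene)
    assert len(whole) == 3 * 141
    assert all(v.ref != v.alt for v in whole)
    single = enumerate_possible_snvs(u4_gene, 120_291_841, 120_291_841)
    assert {(v.ref, v.alt) for v in single} == {("A", "C"), ("A", "G"), ("A", "T")}


def test_sequence_identity(u4_gene, u4_paralog):
    assert sequence_identity(u4_gene.sequence, u4_paralog.sequence) == 97.2
    assert sequence_identity("ACGT", "ACGT") == 100.0
    assert sequence_identity("AAAA", "CCCC") == 0.0
    with pytest.raises(ValueError):
        sequence_identity("ACG", "ACGT")


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

FASTA = ">chrT\nACGTACGTACGTACGTACGT\n"


def test_load_annotation_gtf(tmp_path):
    gtf = tmp_path / "genes.gtf"
    gtf.write_text(
        'chrT\ttest\tgene\t1\t6\t.\t+\t.\tgene_id "gplus"; gene_name "GPLUS"; gene_biotype "snRNA";\n'
        'chrT\ttest\tgene\t1\t6\t.\t-\t.\tgene_id "gminus"; gene_name "GMINUS"; gene_biotype "snRNA";\n'
    )
    fasta = tmp_path / "chrT.fa"
    fasta.write_text(FASTA)
    genes = {g.gene_id: g for g in load_annotation(gtf, fasta)}
    assert genes["gplus"].sequence == "ACGTAC"
    assert genes["gminus"].sequence == reverse_complement("ACGTAC") == "GTACGT"
    assert genes["gplus"].biotype == "snRNA"


def test_load_annotation_bed_convention(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chrT\t0\t6\tgbed\t0\t+\n")  # 0-based half-open 0..6
    fasta = tmp_path / "chrT.fa"
    fasta.write_text(FASTA)
    (gene,) = load_annotation(bed, fasta)
    assert (gene.start, gene.end) == (1, 6)  # 1-based inclusive
    assert gene.sequence == "ACGTAC"


def test_load_annotation_errors(tmp_path):
    fasta = tmp_path / "chrT.fa"
    fasta.write_text(FASTA)
    bad_bed = tmp_path / "bad.bed"
    bad_bed.write_text("chrT\t0\t6\n" "chrT\tnot_a_number\t9\n")
    with pytest.raises(ValueError, match="bad.bed:2"):
        load_annotation(bad_bed, fasta)
    missing = tmp_path / "missing.bed"
    missing.write_text("chrZ\t0\t6\tg\n")
    with pytest.raises(KeyError, match="chrZ"):
        load_annotation(missing, fasta)


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def _gene(gene_id, name, biotype="snRNA"):
    return GeneLocus(gene_id, "chrT", "+", 1, 4, "ACGT", name=name, biotype=biotype)


def test_select_snrna_genes_rules():
    expression = pd.DataFrame(
        {"s1": [6.0, 5.0, 9.0, 9.0], "s2": [6.0, 5.0, 9.0, 9.0], "s3": [6.0, 5.0, 9.0, 9.0]},
        index=["keep", "at_threshold", "pseudo", "listed"],
    )
    genes = [
        _gene("keep", "GOODSN1"),
        _gene("at_threshold", "GOODSN2"),
        _gene("pseudo", "SNRNA99P"),
        _gene("listed", "GOODSN3"),
        _gene("unexpressed", "GOODSN4"),
    ]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        kept = select_snrna_genes(genes, expression, min_mean_cpm=5.0, exclude=["listed"])
    assert [g.gene_id for g in kept] == ["keep"]  # strict >5; pseudogene and listed dropped
    assert any("unexpressed" in str(w.message) or "GOODSN4" in str(w.message) for w in caught)


def test_select_snrna_genes_count_shape():
    # 30 candidates, one pseudogene-named and one at the threshold -> 28 kept
    genes = [_gene(f"g{i}", f"SN{i}") for i in range(28)]
    genes.append(_gene("g_pseudo", "SN900P"))
    genes.append(_gene("g_low", "SN901"))
    expr = pd.DataFrame(
        {"s1": [8.0] * 29 + [5.0]},
        index=[g.gene_id for g in genes],
    )
    kept = select_snrna_genes(genes, expr, min_mean_cpm=5.0)
    assert len(kept) == 28
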