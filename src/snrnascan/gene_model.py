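"""Small-gene loci with bidirectional genomic/transcript coordinate mapping.

Small non-coding RNA genes (snRNAs such as the U4 genes) are short enough —
around 141 bp — that every analysis here works on the full per-base locus:
the gene's transcript sequence, an HGVS-style ``n.`` coordinate system
(1-based from the transcript 5' end), and the set of all possible
single-nucleotide substitutions.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (VCF convention). BED input is
  converted at the boundary.
* ``GeneLocus.sequence`` is stored in transcript orientation (5'->3'), so a
  minus-strand gene's sequence is the reverse complement of the plus-strand
  genomic interval.
* Insertions and deletions use VCF anchored representation on the plus
  strand (alt = anchor + inserted bases). Mapping to ``n.`` coordinates is
  direct arithmetic: no HGVS 3'-shift normalisation is applied, so an
  insertion between plus-strand positions g and g+1 on a minus-strand gene
  maps to ``n.(n(g+1))_(n(g))ins`` with the inserted bases
  reverse-complemented. This reproduces published variant nomenclature for
  these loci; strict HGVS would sometimes shift insertions 3' within
  homopolymers.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")
NUCLEOTIDES = ("A", "C", "G", "T")


def complement(seq: str) -> str:
    """Complement of a nucleotide string (no reversal)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class OutOfLocusError(ValueError):
    """A genomic position falls outside the gene interval."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the locus sequence."""


@dataclass(frozen=True)
class GeneLocus:
    """A small gene with its genomic interval and transcript sequence.

    Parameters
    ----------
    gene_id : str
        Stable identifier.
    chromosome : str
    strand : {"+", "-"}
    start, end : int
        1-based inclusive genomic interval; ``end - start + 1`` must equal
        ``len(sequence)``.
    sequence : str
        Transcript-orientation nucleotide sequence (A/C/G/T).
    name, biotype : str, optional
        Gene symbol and annotation biotype, used by the expression filter.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    sequence: str
    name: str | None = None
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"start ({self.start}) > end ({self.end})")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length {self.length}"
            )
        seq = self.sequence.upper()
        if set(seq) - set(NUCLEOTIDES):
            raise ValueError(f"sequence contains non-ACGT characters: {set(seq) - set(NUCLEOTIDES)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def transcript_position(self, g: int) -> int:
        """Map genomic position g to transcript (n.) position."""
        if not self.contains(g):
            raise OutOfLocusError(
                f"position {g} outside {self.gene_id} ({self.chromosome}:{self.start}-{self.end})"
            )
        if self.strand == "-":
            return self.end - g + 1
        return g - self.start + 1

    def genomic_position(self, n: int) -> int:
        """Map transcript (n.) position to genomic position."""
        if not 1 <= n <= self.length:
            raise OutOfLocusError(f"n.{n} outside 1..{self.length} of {self.gene_id}")
        if self.strand == "-":
            return self.end - n + 1
        return self.start + n - 1

    def transcript_base(self, n: int) -> str:
        if not 1 <= n <= self.length:
            raise OutOfLocusError(f"n.{n} outside 1..{self.length} of {self.gene_id}")
        return self.sequence[n - 1]

    def plus_strand_base(self, g: int) -> str:
        """Reference (plus-strand) base at genomic position g."""
        t = self.transcript_base(self.transcript_position(g))
        return complement(t) if self.strand == "-" else t


@dataclass(frozen=True)
class TranscriptInterval:
    """An interval in transcript (n.) coordinates, 1-based inclusive."""

    gene_id: str
    n_start: int
    n_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_start <= self.n_end:
            raise ValueError(f"invalid transcript interval n.{self.n_start}-{self.n_end}")

    @property
    def length(self) -> int:
        return self.n_end - self.n_start + 1


@dataclass(frozen=True)
class GenomicVariant:
    """A variant in VCF-style plus-strand representation."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for allele in (self.ref, self.alt):
            if not allele or set(allele.upper()) - set(NUCLEOTIDES):
                raise ValueError(f"invalid allele {allele!r}")

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) == 1 and self.alt.startswith(self.ref):
            return "insertion"
        if len(self.alt) == 1 and self.ref.startswith(self.alt):
            return "deletion"
        return "complex"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    def __str__(self) -> str:  # e.g. chr12:120291839:T:TA
        return f"{self.chromosome}:{self.position}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class TranscriptVariant:
    """A variant expressed in transcript (n.) coordinates.

    ``kind`` is one of ``sub``/``ins``/``del``. For substitutions
    ``n_start == n_end`` and ``ref``/``alt`` are single transcript-strand
    bases. For insertions ``n_start``/``n_end`` are the flanking transcript
    positions (``n_end = n_start + 1``) and ``alt`` holds the inserted
    transcript-strand bases. For deletions the interval is the deleted span.
    """

    gene_id: str
    kind: str
    n_start: int
    n_end: int
    ref: str = ""
    alt: str = ""

    @property
    def n_description(self) -> str:
        if self.kind == "sub":
            return f"n.{self.n_start}{self.ref}>{self.alt}"
        if self.kind == "ins":
            return f"n.{self.n_start}_{self.n_end}ins{self.alt}"
        if self.kind == "del":
            if self.n_start == self.n_end:
                return f"n.{self.n_start}del"
            return f"n.{self.n_start}_{self.n_end}del"
        raise ValueError(f"unknown kind {self.kind!r}")


def genomic_to_transcript(
    gene: GeneLocus, variant: GenomicVariant, validate_ref: bool = True
) -> TranscriptVariant:
    """Map a plus-strand genomic variant into the gene's n. coordinates.

    Substitutions: ``n = end - g + 1`` on the minus strand (alleles
    complemented), ``n = g - start + 1`` on the plus strand. An insertion
    anchored at plus-strand position g (between g and g+1) maps to
    ``n.(n(g))_(n(g)+1)ins`` on the plus strand and ``n.(n(g+1))_(n(g))ins``
    with reverse-complemented bases on the minus strand.
    """
    g = variant.position
    vt = variant.variant_type
    if vt == "SNV":
        n = gene.transcript_position(g)
        if validate_ref and gene.plus_strand_base(g) != variant.ref:
            raise ReferenceMismatchError(
                f"{variant}: locus {gene.gene_id} has {gene.plus_strand_base(g)} at {g}"
            )
        if gene.strand == "-":
            return TranscriptVariant(
                gene.gene_id, "sub", n, n, complement(variant.ref), complement(variant.alt)
            )
        return TranscriptVariant(gene.gene_id, "sub", n, n, variant.ref, variant.alt)
    if vt == "insertion":
        inserted = variant.alt[len(variant.ref):]
        if not (gene.contains(g) and gene.contains(g + 1)):
            raise OutOfLocusError(
                f"insertion {variant} not strictly inside {gene.gene_id}"
            )
        if validate_ref and gene.plus_strand_base(g) != variant.ref:
            raise ReferenceMismatchError(
                f"{variant}: locus {gene.gene_id} has {gene.plus_strand_base(g)} at {g}"
            )
        if gene.strand == "-":
            n_hi = gene.transcript_position(g)        # 3' flank in n. space
            return TranscriptVariant(
                gene.gene_id, "ins", n_hi - 1, n_hi, alt=reverse_complement(inserted)
            )
        n_lo = gene.transcript_position(g)
        return TranscriptVariant(gene.gene_id, "ins", n_lo, n_lo + 1, alt=inserted)
    if vt == "deletion":
        deleted = variant.ref[len(variant.alt):]
        first, last = g + 1, g + len(deleted)
        if not (gene.contains(first) and gene.contains(last)):
            raise OutOfLocusError(f"deletion {variant} not contained in {gene.gene_id}")
        if gene.strand == "-":
            return TranscriptVariant(
                gene.gene_id,
                "del",
                gene.transcript_position(last),
                gene.transcript_position(first),
                ref=reverse_complement(deleted),
            )
        return TranscriptVariant(
            gene.gene_id,
            "del",
            gene.transcript_position(first),
            gene.transcript_position(last),
            ref=deleted,
        )
    raise ValueError(f"cannot map complex variant {variant}")


def transcript_to_genomic(gene: GeneLocus, tv: TranscriptVariant) -> GenomicVariant:
    """Inverse of :func:`genomic_to_transcript`."""
    minus = gene.strand == "-"
    if tv.kind == "sub":
        g = gene.genomic_position(tv.n_start)
        ref = complement(tv.ref) if minus else tv.ref
        alt = complement(tv.alt) if minus else tv.alt
        return GenomicVariant(gene.chromosome, g, ref, alt)
    if tv.kind == "ins":
        # anchor is the plus-strand position 5' of the insertion point
        g = gene.genomic_position(tv.n_end) if minus else gene.genomic_position(tv.n_start)
        anchor = gene.plus_strand_base(g)
        inserted = reverse_complement(tv.alt) if minus else tv.alt
        return GenomicVariant(gene.chromosome, g, anchor, anchor + inserted)
    if tv.kind == "del":
        if minus:
            first = gene.genomic_position(tv.n_end)
        else:
            first = gene.genomic_position(tv.n_start)
        g = first - 1
        if not gene.contains(g):
            raise OutOfLocusError(
                f"deletion anchor {g} outside {gene.gene_id}; cannot express in VCF form"
            )
        anchor = gene.plus_strand_base(g)
        deleted = reverse_complement(tv.ref) if minus else tv.ref
        return GenomicVariant(gene.chromosome, g, anchor + deleted, anchor)
    raise ValueError(f"unknown kind {tv.kind!r}")


def genomic_region_to_transcript(gene: GeneLocus, g_start: int, g_end: int) -> TranscriptInterval:
    """Map a genomic interval to an ascending transcript interval."""
    if g_start > g_end:
        g_start, g_end = g_end, g_start
    if not (gene.contains(g_start) and gene.contains(g_end)):
        raise OutOfLocusError(
            f"{gene.chromosome}:{g_start}-{g_end} not contained in {gene.gene_id}"
        )
    a = gene.transcript_position(g_start)
    b = gene.transcript_position(g_end)
    return TranscriptInterval(gene.gene_id, min(a, b), max(a, b))


def transcript_region_to_genomic(gene: GeneLocus, interval: TranscriptInterval) -> tuple[int, int]:
    a = gene.genomic_position(interval.n_start)
    b = gene.genomic_position(interval.n_end)
    return (min(a, b), max(a, b))


def enumerate_possible_snvs(
    gene: GeneLocus, g_start: int | None = None, g_end: int | None = None
) -> list[GenomicVariant]:
    """All 3 alternative substitutions at every position of the interval.

    Returns exactly ``3 * interval_length`` plus-strand variants; defaults to
    the whole gene.
    """
    g_start = gene.start if g_start is None else g_start
    g_end = gene.end if g_end is None else g_end
    if g_start > g_end:
        raise ValueError(f"empty interval {g_start}-{g_end}")
    if not (gene.contains(g_start) and gene.contains(g_end)):
        raise OutOfLocusError(f"{g_start}-{g_end} not contained in {gene.gene_id}")
    out = []
    for g in range(g_start, g_end + 1):
        ref = gene.plus_strand_base(g)
        for alt in NUCLEOTIDES:
            if alt != ref:
                out.append(GenomicVariant(gene.chromosome, g, ref, alt))
    return out


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two equal-length sequences, one decimal."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal lengths: {len(seq_a)} vs {len(seq_b)}")
    if not seq_a:
        raise ValueError("empty sequences")
    matches = sum(a == b for a, b in zip(seq_a.upper(), seq_b.upper()))
    return round(100.0 * matches / len(seq_a), 1)


# ---------------------------------------------------------------------------
# annotation / sequence I/O
# ---------------------------------------------------------------------------

def load_annotation(
    annotation_file: str | Path,
    sequence_file: str | Path,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneLocus]:
    """Read gene loci from GTF/GFF3 or BED plus a FASTA of their chromosomes.

    Minus-strand sequences are reverse-complemented into transcript
    orientation. BED is interpreted as 0-based half-open and converted to
    the internal 1-based inclusive convention.
    """
    import pyfaidx

    annotation_file = Path(annotation_file)
    fasta = pyfaidx.Fasta(str(sequence_file))
    records: list[tuple[str, str, int, int, str, str | None, str | None]] = []
    if annotation_file.suffix.lower() == ".bed":
        records = _read_bed(annotation_file)
    else:
        records = _read_gff(annotation_file, feature_types)

    genes = []
    for gene_id, chrom, start, end, strand, name, biotype in records:
        if chrom not in fasta:
            raise KeyError(f"no sequence for chromosome {chrom!r} (gene {gene_id})")
        seq = str(fasta[chrom][start - 1 : end]).upper()
        if len(seq) != end - start + 1:
            raise ValueError(
                f"FASTA for {chrom} does not cover {start}-{end} (gene {gene_id})"
            )
        if strand == "-":
            seq = reverse_complement(seq)
        genes.append(
            GeneLocus(gene_id, chrom, strand, start, end, seq, name=name, biotype=biotype)
        )
    return genes


def _read_bed(path: Path):
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: malformed BED line (<3 columns)")
            try:
                chrom = fields[0]
                start0, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"region_{i}"
            strand = fields[5] if len(fields) > 5 else "+"
            records.append((name, chrom, start0 + 1, end, strand, name, None))
    return records


def _read_gff(path: Path, feature_types: Sequence[str]):
    import gffutils.iterators

    records = []
    for i, feature in enumerate(gffutils.iterators.DataIterator(str(path)), start=1):
        try:
            if feature.featuretype not in feature_types:
                continue
            attrs = feature.attributes
            gene_id = _first_attr(attrs, "gene_id", "ID", "Name")
            if gene_id is None:
                raise ValueError("no gene_id/ID attribute")
            name = _first_attr(attrs, "gene_name", "Name") or gene_id
            biotype = _first_attr(attrs, "gene_biotype", "gene_type", "biotype")
            records.append(
                (gene_id, feature.seqid, feature.start, feature.end, feature.strand, name, biotype)
            )
        except Exception as exc:
            raise ValueError(f"{path}: record {i}: {exc}") from exc
    return records


def _first_attr(attrs, *keys):
    for key in keys:
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return None


_PSEUDOGENE_NAME = re.compile(r"P\d*$")


def select_snrna_genes(
    genes: Iterable[GeneLocus],
    expression: pd.DataFrame,
    min_mean_cpm: float = 5.0,
    exclude: Iterable[str] = (),
    use_name_heuristic: bool = True,
) -> list[GeneLocus]:
    """Select expressed, non-pseudogene snRNA genes.

    A gene is retained when it is not on the explicit ``exclude`` list (the
    curated pseudogene list; this wins over the heuristic), its name does not
    carry a trailing P-designation (``...P`` or ``...P<digits>``) when
    ``use_name_heuristic`` is set, its biotype (if recorded) is not a
    pseudogene biotype, and its mean expression across all samples in
    ``expression`` (a genes x samples CPM DataFrame) is strictly greater
    than ``min_mean_cpm``. Genes absent from the expression table are
    excluded with a warning.
    """
    exclude = set(exclude)
    kept = []
    for gene in genes:
        label = gene.name or gene.gene_id
        if gene.gene_id in exclude or label in exclude:
            continue
        if gene.biotype and "pseudogene" in gene.biotype.lower():
            continue
        if use_name_heuristic and gene.name and _PSEUDOGENE_NAME.search(gene.name):
            continue
        row = None
        if gene.gene_id in expression.index:
            row = expression.loc[gene.gene_id]
        elif gene.name is not None and gene.name in expression.index:
            row = expression.loc[gene.name]
        if row is None:
            warnings.warn(
                f"gene {label} absent from expression table; excluded", stacklevel=2
            )
            continue
        if float(row.mean()) > min_mean_cpm:
            kept.append(gene)
    return kept
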