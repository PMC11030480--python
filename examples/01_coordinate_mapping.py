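"""Map variants between genomic and transcript (n.) coordinates.

Small non-coding genes on the minus strand have their HGVS-style n.
numbering running opposite to genomic coordinates, with alleles
complemented. This example maps the recurrent single-base insertion and a
substitution of the U4-like locus both ways.
"""

from snrnascan import GenomicVariant, genomic_region_to_transcript, genomic_to_transcript, transcript_to_genomic
from snrnascan.simulate import u4_like_gene

gene = u4_like_gene()
print(f"{gene.gene_id}: {gene.chromosome}:{gene.start}-{gene.end} ({gene.strand}), {gene.length} bp")

for variant in (
    GenomicVariant("chr12", 120_291_839, "T", "TA"),   # recurrent insertion
    GenomicVariant("chr12", 120_291_841, "A", "C"),    # substitution
):
    tv = genomic_to_transcript(gene, variant)
    back = transcript_to_genomic(gene, tv)
    print(f"  {variant}  ->  {tv.n_description}  ->  {back}")

region = genomic_region_to_transcript(gene, 120_291_825, 120_291_842)
print(f"critical region chr12:120,291,825-120,291,842 -> n.{region.n_start}-{region.n_end}")
# The insertion anchored at plus-strand T:TA lands between transcript
# nucleotides 64 and 65 as an inserted T, because the gene is minus-strand;
# the 18-bp genomic region maps to transcript nucleotides 62-79.
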