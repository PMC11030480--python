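from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snrnascan.constraint import PopulationVariantTable
from snrnascan.gene_model import GeneLocus
from snrnascan.simulate import u4_like_gene, u4_paralog_gene


@pytest.fixture
def plus_gene() -> GeneLocus:
    # transcript base at n.6 is A so chr1:105 A>G maps to n.6A>G
    return GeneLocus("PLUS1", "chr1", "+", 100, 111, "ACGTAACGTACG")


@pytest.fixture
def minus_gene() -> GeneLocus:
    # same interval on the minus strand; transcript = revcomp of plus-strand seq
    return GeneLocus("MINUS1", "chr1", "-", 100, 111, "CGTACGTTACGT")


@pytest.fixture
def u4_gene() -> GeneLocus:
    return u4_like_gene()


@pytest.fixture
def u4_paralog() -> GeneLocus:
    return u4_paralog_gene()


def make_population(variants, an: int = 981_280, cohort_size: int | None = None):
    """PopulationVariantTable from (chrom, pos, ref, alt[, ac]) tuples."""
    rows = []
    for v in variants:
        chrom, pos, ref, alt = v[:4]
        ac = v[4] if len(v) > 4 else 1
        rows.append(
            {"chromosome": chrom, "position": pos, "ref": ref, "alt": alt, "ac": ac, "an": an}
        )
    df = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt", "ac", "an"])
    return PopulationVariantTable(df, cohort_size=cohort_size)


@pytest.fixture
def population_factory():
    return make_population
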