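"""Phenotype-term collapsing and carrier enrichment tests.

Probands are annotated with raw ontology codes (HPO terms, ICD-10 codes);
clinically related codes are collapsed into a single phenotype group via an
explicit mapping list (no ontology-graph propagation), and each group is
tested for enrichment among variant carriers versus comparator probands
with Fisher's exact test. Groups observed in fewer carriers than a minimum
(default 5) are not tested. No multiple-testing correction is applied here;
raw p-values are emitted with a significance flag at a user-chosen alpha.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .burden import ContingencyTable, fisher_exact

logger = logging.getLogger(__name__)


def load_term_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (code, group) -> mapping; a code maps to one group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["code", "group"], comment="#")
    dupes = df[df["code"].duplicated()]
    if len(dupes):
        raise ValueError(f"codes mapped to multiple groups: {list(dupes['code'])}")
    return dict(zip(df["code"], df["group"]))


def collapse_terms(
    proband_terms: Mapping[str, Iterable[str]] | pd.DataFrame,
    term_map: Mapping[str, str],
) -> dict[str, set[str]]:
    """Collapse each proband's raw codes into a set of phenotype groups.

    ``proband_terms`` is either {proband: codes} or a long-format DataFrame
    with columns proband_id/code. Codes not in the map are ignored; their
    count is logged.
    """
    if isinstance(proband_terms, pd.DataFrame):
        grouped = proband_terms.groupby("proband_id")["code"].apply(list)
        proband_terms = dict(grouped)
    out: dict[str, set[str]] = {}
    unmapped = 0
    for proband, codes in proband_terms.items():
        groups = set()
        for code in codes:
            group = term_map.get(code)
            if group is None:
                unmapped += 1
            else:
                groups.add(group)
        out[str(proband)] = groups
    if unmapped:
        logger.info("collapse_terms: %d raw codes had no group mapping", unmapped)
    return out


def build_phenotype_counts(
    groups_by_proband: Mapping[str, set[str]],
    carriers: Iterable[str],
    comparators: Iterable[str],
) -> pd.DataFrame:
    """Per-group carrier/comparator counts.

    Probands missing from ``groups_by_proband`` count as having no groups.
    """
    carriers = list(dict.fromkeys(carriers))
    comparators = list(dict.fromkeys(comparators))
    groups = sorted({g for p in (*carriers, *comparators) for g in groups_by_proband.get(p, ())})
    rows = []
    for group in groups:
        rows.append(
            {
                "group": group,
                "carriers_with": sum(group in groups_by_proband.get(p, ()) for p in carriers),
                "carriers_total": len(carriers),
                "comparators_with": sum(group in groups_by_proband.get(p, ()) for p in comparators),
                "comparators_total": len(comparators),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "carriers_with", "carriers_total", "comparators_with", "comparators_total"],
    )


def enrich_phenotypes(
    counts: pd.DataFrame,
    min_carriers: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact test per phenotype group among carriers vs comparators.

    Groups present in fewer than ``min_carriers`` carriers are excluded.
    Returns group, counts, conditional-MLE OR with exact CI, raw p, and a
    flag column at ``alpha`` (no multiplicity correction).
    """
    rows = []
    for rec in counts.itertuples(index=False):
        if rec.carriers_with < min_carriers:
            continue
        table = ContingencyTable.from_carriers(
            int(rec.carriers_with), int(rec.carriers_total),
            int(rec.comparators_with), int(rec.comparators_total),
        )
        res = fisher_exact(table)
        rows.append(
            {
                "group": rec.group,
                "carriers_with": int(rec.carriers_with),
                "carriers_total": int(rec.carriers_total),
                "comparators_with": int(rec.comparators_with),
                "comparators_total": int(rec.comparators_total),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "carriers_with", "carriers_total", "comparators_with",
            "comparators_total", "odds_ratio", "ci_low", "ci_high", "p_value", "significant",
        ],
    )
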