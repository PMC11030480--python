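"""Exact 2x2 burden statistics on published cohort counts.

Runs Fisher's exact test (conditional-MLE odds ratio, exact CI) on the
published carrier counts, plus the cohort arithmetic around them.
"""

from snrnascan import (
    ContingencyTable,
    allele_balance,
    allele_frequency,
    carrier_fraction,
    extrapolated_prevalence,
    fisher_exact,
)

tables = {
    "critical region (60/8,841 vs 39/490,132)":
        ContingencyTable.from_carriers(60, 8841, 39, 490_132),
    "insertions (54/8,841 vs 2/490,132)":
        ContingencyTable.from_carriers(54, 8841, 2, 490_132),
    "SNVs (6/8,841 vs 35/490,132)":
        ContingencyTable.from_carriers(6, 8841, 35, 490_132),
    "remainder of gene (194/7,519 vs 521/19,428)":
        ContingencyTable.from_carriers(194, 7519, 521, 19_428),
}
for label, table in tables.items():
    res = fisher_exact(table)
    hi = "inf" if res.ci_high == float("inf") else f"{res.ci_high:.1f}"
    print(f"{label}: OR {res.odds_ratio:.4g} (95% CI {res.ci_low:.4g}-{hi}), p {res.p_value:.3g}")

print(f"carrier fraction 46/8,841            = {carrier_fraction(46, 8841):.2f}%")
print(f"carrier fraction 60/8,841            = {carrier_fraction(60, 8841):.2f}%")
print(f"prevalence with 40% prior diagnoses  = {extrapolated_prevalence(60, 8841, 0.4):.2f}%")
print(f"allele frequency 1 / 490,640 genomes = {allele_frequency(1, 490_640):.3g}")
print(f"allele balance 18 alt / 23 ref reads = {100 * allele_balance(23, 18):.0f}%")
# The conditional-MLE odds ratio is the estimate fisher.test in R reports;
# it differs from the sample cross-product ratio, especially for tables
# with small cells.
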