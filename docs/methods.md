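# Methods

This note documents the models and procedures implemented in `snrnascan`,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Constraint scan

For a gene of length *L* with transcript coordinates `n.1..L`, every
window of *w* consecutive bases (default *w* = 18, step 1, giving
*L* − *w* + 1 windows) is scored as

    proportion = (# distinct possible SNVs observed in the population) / (3w)

A "possible SNV" is one of the three alternative substitutions at a
reference position; a population record counts toward the numerator only
if it is a single-nucleotide substitution whose REF matches the locus
(indels are tallied separately and never enter the proportion), and a
multi-allelic site contributes one unit per distinct alternate. Window
proportions are normalised by subtracting the per-gene **median** window
proportion, so the statistic measures depletion relative to the gene
itself rather than to a mutation-rate model — deliberate, because snRNA
loci are hypermutable enough that absolute rates are poorly calibrated,
and the question is where within the gene variation is missing.

Windows with normalised proportion ≤ −0.2 qualify as depleted. The
comparison is inclusive ("a deviation of at least 20%"), with an
`inclusive=False` switch, and uses a 1e-9 tie tolerance so a window
sitting exactly at the threshold up to float noise from the median
subtraction behaves deterministically. Qualifying windows whose extents
overlap or touch are merged; the called region is the **union** of the
member windows' extents. Because every window overlapping a constrained
element by roughly ⌈w·(q_out−q_in−0.2)/(q_out−q_in)⌉ bases falls below the
threshold, the union extent is systematically wider than the element —
about 10 bp on each side under the default simulation probabilities. Each
region therefore also records its **core**: the single most-depleted
window (ties broken 5'-most), which is the right point estimate of the
element's location and in simulations recovers the planted 18-bp region's
boundaries to within ~1 bp. An intersection-extent mode exists behind a
flag but is empty whenever qualifying windows span more than *w* offsets.

No allele-frequency filter is applied to "observed" variants: rarity of
the standing variation is itself evidence of selection, not a QC
criterion.

## Intergenic null

The sampling pool is the complement, on one chromosome, of all annotated
transcripts padded by a buffer (default 10 kbp) and of explicit exclusion
intervals (e.g. the centromere), keeping only intervals at least as long
as the region length (default 141 bp). Fixed-length regions (default
1,000 of them) are placed by sequential rejection: a start is drawn
uniformly over all valid placements and redrawn if it overlaps an already
placed region. Capacity is checked up front (Σ⌊interval/length⌋) and the
sampler aborts with the achievable maximum if asked for more. For the
pool densities in practice (regions cover ≪ 1% of the pool) rejection is
effectively uniform and deterministic under a seed.

Each region (and each gene) is summarised by the **median** of its
sliding-window proportions. The two groups of summaries are compared with
a one-way Fisher-Pitman permutation test: statistic = difference of group
means (the classical choice; a median-statistic option exists), null
generated by reallocating the pooled summaries to groups of the original
sizes. With B Monte-Carlo reallocations the add-one-corrected
p = (1 + #{permuted ≥ observed})/(1 + B), so the smallest attainable p at
B = 1,000 is 1/1001 ≈ 0.000999; when the number of distinct allocations is
below a cap (default 10^5) the exact tail fraction is computed instead.
If all pooled values are identical the test is degenerate and returns
p = 1 with a warning. The gene group enters jointly (e.g. both U4
paralogs, n = 2): the test is then extremely discrete, which is why the
Monte-Carlo minimum, not a tiny asymptotic p, is the reportable result.

## Exact 2×2 statistics

Conditioning on both margins of a 2×2 table, the first cell follows
Fisher's noncentral hypergeometric distribution with noncentrality ψ equal
to the odds ratio. `fisher_exact` reports:

* **p-value** (two-sided): the sum of conditional probabilities at ψ = 1
  not exceeding the observed one, with a 1 + 1e-7 relative tie tolerance
  (the convention of R's `fisher.test`, which published values follow).
  One-sided alternatives are plain tail sums.
* **odds ratio**: the conditional MLE, i.e. the ψ solving E_ψ[X] = x,
  found by Brent root-finding on ψ ∈ (0, 1) or reciprocally on 1/ψ.
  This estimate — not the sample cross-product ad/bc, which is also
  reported as a secondary field — is what exact-test software prints, and
  the two differ noticeably for tables with small cells.
* **confidence interval**: exact tail inversion, P_ψ(X ≥ x) = α/2 at the
  lower limit and P_ψ(X ≤ x) = α/2 at the upper, each found the same way.
  An observed count at the support boundary yields 0 or ∞ bounds (and a
  0/∞ estimate), serialised as a distinguished `"inf"` marker in JSON.

The root solver deliberately reproduces R's `uniroot` scheme, including
its default tolerance (machine-ε^0.25 on the bracketing scale), so that
estimates agree digit-for-digit with what R-based analyses publish; a
`tol` argument (e.g. `1e-12`) gives maximum-precision roots instead. The
distinction matters only where the conditional likelihood is nearly flat:
for a table like 54/8,787 vs 2/490,130 the estimate is determined only to
about a percent by *any* solver at R's tolerance (the exact MLE is
1505.9; R builds print values in the 1,500–1,550 range), so
published-value reproduction at such tables is inherently approximate.
The test suite verifies the precise-tolerance path against an independent
brute-force oracle (integer-weight tail sums and grid-search likelihood
maximisation) on every 2×2 table with all margins ≤ 30.

Burden screens build carriers-vs-rest tables (carriers, total − carriers)
per unit, include units with at least `min_case_dnvs` (default 2) case de
novo variants, and flag significance at α/n_tests (Bonferroni, α = 0.05).
The recurrent-variant screen retains case variants with allele count
≥ 3 that are absent from every comparator cohort and have population
allele frequency ≤ 0.5%.

Cohort arithmetic: carrier fractions are plain percentages;
`extrapolated_prevalence(c, n, r) = 100·c/(n/(1−r))` converts a prevalence
among an undiagnosed cohort into a prevalence among all affected
individuals assuming a fraction r was diagnosed upstream (default 0.4).

## Phenotype enrichment

Raw HPO/ICD-10 codes collapse to phenotype groups through an explicit
two-column mapping (each code to at most one group); no ontology-graph
ancestor closure is performed, matching how such term lists are curated in
practice. Groups observed in fewer than `min_carriers` (default 5)
carriers are not tested; the rest get `fisher_exact` on carriers vs
comparators. Raw p-values are reported with a flag at a user-chosen α and
no multiplicity correction — the test count here is small and
reader-facing.

## Synthetic data

The generator's defaults are the documented study conditions, not free
dials:

| parameter | default | meaning |
|---|---|---|
| q_out / q_in | 0.78 / 0.26 | per-possible-SNV observation probability outside/inside the planted region |
| constrained region | n.62–79 | planted 18-bp element of the focal 141-bp minus-strand gene |
| af_max | 2.5×10⁻⁴ | cap on simulated population allele frequency |
| population_size | 490,640 | individuals behind the population table |
| n_case / n_control | 5,426 / 4,776 | trio-arm proband counts |
| dnv_rate | 5×10⁻⁴ | de novo variants per proband per gene |
| region_enrichment ρ | 100 | case in-region rate multiplier (≈35 expected in-region case DNVs) |
| insertion_weight | 0.773 | fraction of in-region case variants that are the fixed hotspot insertion |
| intergenic_q | 0.13 | per-possible-SNV observation probability in null regions |

Observed allele counts follow a geometric tail (p = 0.1) truncated at
af_max — only the AF ceiling is documented for the real data, so the tail
shape is a modelling choice and nothing downstream depends on it. Decoy
genes are simulated with q_in = q_out (no constraint) to give the screens
true negatives. Phenotype groups default to four with baselines and
planted odds ratios consistent with the published carrier counts (e.g.
global developmental delay p₀ = 0.54, OR 3.56; drooling p₀ = 0.009, OR
19.2); carrier probabilities solve odds(p₁) = OR·odds(p₀). The recurrent
hotspot is modelled as a fixed weight on one insertion, not as a
mechanistic secondary-structure mutation model. The bundled loci use the
documented coordinates, strand and length, but their sequences are
pseudo-random (**synthetic**), with the few transcript positions appearing
in the documented nomenclature examples pinned so those examples hold.

What passing synthetic tests shows: the scan, null test, screens and
enrichment recover planted structure of the documented magnitude, with
exact-CI coverage at nominal rates. What it does not show: behaviour under
real mutational sequence context, calling artefacts, cohort relatedness or
phenotype ascertainment — all absorbed into independence assumptions here.
Published per-gene observed proportions, per-term odds ratios whose
comparator counts are unpublished, and the real 14-region screen result
cannot be recomputed without the access-controlled datasets.

## Numerical and design choices

* Coordinates are 1-based inclusive internally (VCF convention); BED I/O
  converts at the boundary. Minus-strand insertions map by direct
  arithmetic with no HGVS 3'-shift normalisation — shifting would move the
  hotspot insertion's name within its homopolymer context away from its
  published form; this deviation from strict HGVS is intentional.
* Expression filtering is strictly greater-than (mean CPM > 5), and an
  explicit curated pseudogene exclusion list always wins over the trailing
  "P-designation" name heuristic.
* Window step is 1 bp: region boundaries are reported at single-base
  resolution and the gene lengths involved make the cost trivial.
* Determinism: every stochastic component takes a seed or Generator;
  the pipeline derives purpose-keyed generators from one seed, and
  identical configuration yields byte-identical output files. The run
  manifest (version, seed, config hash) suffices to reproduce a run.
* Problem sizes in the test suite and acceptance script (e.g. 25–100
  simulation seeds, 1,000 null regions, 500 calibration replicates) were
  chosen as the smallest sizes at which the stochastic checks have
  comfortable margins of error.

## Known limitations

* The intergenic null is sampled by sequential rejection, not by the
  two-stage per-interval scheme some analyses describe; both target a
  uniform non-overlapping sample, and for sparse packing they coincide in
  distribution.
* `fisher_exact` handles 2×2 tables only; log-linear or covariate-adjusted
  association is out of scope.
* The annotation reader handles gene-level GTF/GFF3/BED records for small
  loci; it is not a general-purpose genome annotation engine, and no
  assembly liftover is provided.
* The Fisher-Pitman test with a gene group of n = 2 has a coarse attainable
  p-value set; interpret only against the Monte-Carlo minimum.
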