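"""Synthetic-cohort generator: planted structure, determinism, recovery."""

from __future__ import annotations

import json

import numpy as np
import pytest

from snrnascan.burden import fisher_exact
from snrnascan.gene_model import genomic_region_to_transcript
from snrnascan.simulate import (
    SimulationConfig,
    simulate_cohorts,
    simulate_denovo_cohorts,
    simulate_phenotypes,
    simulate_population,
    solve_carrier_probability,
    u4_like_gene,
    u4_paralog_gene,
    write_cohorts,
)


def small_config(**kwargs) -> SimulationConfig:
    defaults = dict(
        genes=(u4_like_gene(), u4_paralog_gene()),
        population_size=10_000,
        n_case=500,
        n_control=500,
        seed=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def _region_bounds(config):
    gene = config.focal_gene
    lo, hi = config.constrained_region
    return sorted((gene.genomic_position(lo), gene.genomic_position(hi)))


def test_q_in_zero_empties_the_region():
    config = small_config(q_in=0.0)
    pop = simulate_population(config)
    g_lo, g_hi = _region_bounds(config)
    in_region = pop.df[(pop.df["position"] >= g_lo) & (pop.df["position"] <= g_hi)]
    assert len(in_region) == 0


def test_q_out_one_saturates_outside_region():
    config = small_config(q_out=1.0)
    pop = simulate_population(config)
    focal = config.focal_gene
    g_lo, g_hi = _region_bounds(config)
    outside = pop.df[
        (pop.df["position"] >= focal.start)
        & (pop.df["position"] <= focal.end)
        & ~((pop.df["position"] >= g_lo) & (pop.df["position"] <= g_hi))
    ]
    assert len(outside) == 3 * (141 - 18)


def test_out_of_region_count_is_binomial():
    config = small_config()
    counts = []
    for seed in range(20):
        pop = simulate_population(small_config(seed=seed))
        focal = config.focal_gene
        g_lo, g_hi = _region_bounds(config)
        outside = pop.df[
            (pop.df["position"] >= focal.start)
            & (pop.df["position"] <= focal.end)
            & ~((pop.df["position"] >= g_lo) & (pop.df["position"] <= g_hi))
        ]
        counts.append(len(outside))
    n, q = 3 * (141 - 18), 0.78
    sd = np.sqrt(n * q * (1 - q))
    assert abs(np.mean(counts) - n * q) < 3 * sd / np.sqrt(len(counts))


def test_allele_frequency_cap():
    config = small_config(seed=3)
    pop = simulate_population(config)
    assert pop.max_allele_frequency() <= config.af_max + 1e-12


def test_insertion_weight_one_makes_all_in_region_case_variants_identical():
    config = small_config(insertion_weight=1.0, region_enrichment=200.0, dnv_rate=2e-3)
    case, _ = simulate_denovo_cohorts(config)
    g_lo, g_hi = _region_bounds(config)
    in_region = case[(case["position"] >= g_lo) & (case["position"] <= g_hi)]
    assert len(in_region) > 0
    assert in_region["n_description"].nunique() == 1
    assert in_region["n_description"].iloc[0] == "n.64_65insT"


def test_null_enrichment_covers_unity():
    """With rho = 1 the in-region case/control exact CI covers OR = 1."""
    covered = 0
    n_seeds = 60
    for seed in range(n_seeds):
        config = small_config(
            seed=seed, region_enrichment=1.0, dnv_rate=5e-2, n_case=2000, n_control=2000
        )
        case, control = simulate_denovo_cohorts(config)
        g_lo, g_hi = _region_bounds(config)
        a = case[(case["position"] >= g_lo) & (case["position"] <= g_hi)]["proband_id"].nunique()
        c = control[(control["position"] >= g_lo) & (control["position"] <= g_hi)]["proband_id"].nunique()
        res = fisher_exact(((a, 2000 - a), (c, 2000 - c)))
        if res.ci_low <= 1.0 <= res.ci_high:
            covered += 1
    assert covered >= int(0.93 * n_seeds)


def test_planted_enrichment_recovered_within_ci():
    """The exact CI covers the planted in-region carrier odds ratio."""
    config0 = small_config()
    w, L = 18, 141
    p_case = 1 - np.exp(-config0.dnv_rate * config0.region_enrichment * w / L)
    p_ctrl = 1 - np.exp(-config0.dnv_rate * w / L)
    planted_or = (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))
    covered = 0
    n_seeds = 50
    for seed in range(n_seeds):
        config = small_config(seed=seed, n_case=5426, n_control=4776)
        case, control = simulate_denovo_cohorts(config)
        g_lo, g_hi = _region_bounds(config)
        a = case[(case["position"] >= g_lo) & (case["position"] <= g_hi)]["proband_id"].nunique()
        c = control[(control["position"] >= g_lo) & (control["position"] <= g_hi)]["proband_id"].nunique()
        res = fisher_exact(((a, 5426 - a), (c, 4776 - c)))
        if res.ci_low <= planted_or <= res.ci_high:
            covered += 1
    assert covered >= int(0.93 * n_seeds)


def test_phenotype_probability_solver():
    assert solve_carrier_probability(0.5, 1.0) == pytest.approx(0.5)
    assert solve_carrier_probability(0.5, 9.0) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        solve_carrier_probability(0.5, 0.0)


def test_planted_phenotype_odds_ratio_recovered():
    from snrnascan.phenotypes import build_phenotype_counts, collapse_terms, enrich_phenotypes

    # a rare phenotype: at these counts the exact CI is distinctly
    # conservative, so the >= 93/100 coverage bound has real slack
    groups = {"grp": (0.02, 3.5)}
    term_map = {"CODE1": "grp"}
    carriers = [f"c{i}" for i in range(500)]
    noncarriers = [f"n{i}" for i in range(5000)]
    covered = 0
    n_seeds = 100
    for seed in range(n_seeds):
        terms = simulate_phenotypes(
            carriers, noncarriers, groups=groups, term_map=term_map, seed=seed
        )
        collapsed = collapse_terms(terms, term_map)
        counts = build_phenotype_counts(collapsed, carriers, noncarriers)
        row = enrich_phenotypes(counts, min_carriers=5).iloc[0]
        if row["ci_low"] <= 3.5 <= row["ci_high"]:
            covered += 1
    assert covered >= 93


def test_determinism_byte_identical(tmp_path):
    config = small_config(seed=11)
    paths1 = write_cohorts(simulate_cohorts(config), tmp_path / "run1")
    paths2 = write_cohorts(simulate_cohorts(small_config(seed=11)), tmp_path / "run2")
    for key in paths1:
        assert paths1[key].read_bytes() == paths2[key].read_bytes(), key
    different = write_cohorts(simulate_cohorts(small_config(seed=12)), tmp_path / "run3")
    assert paths1["population_vcf"].read_bytes() != different["population_vcf"].read_bytes()


def test_truth_records_all_planted_parameters(tmp_path):
    config = small_config(seed=2)
    cohorts = simulate_cohorts(config)
    truth = cohorts.truth
    for key in (
        "q_out", "q_in", "af_max", "dnv_rate", "region_enrichment",
        "insertion_weight", "hotspot", "constrained_region_n", "seed",
    ):
        assert key in truth
    assert truth["constrained_region_genomic"] == [120_291_825, 120_291_842]
    paths = write_cohorts(cohorts, tmp_path / "out")
    assert json.loads(paths["truth"].read_text()) == truth


def test_every_simulated_variant_lies_in_a_configured_gene():
    config = small_config(seed=4)
    cohorts = simulate_cohorts(config)
    spans = [(g.start, g.end) for g in config.genes]
    for df in (cohorts.population.df, cohorts.case_dnvs, cohorts.control_dnvs):
        pos = df["position"]
        assert all(any(s <= p <= e + 0 for s, e in spans) for p in pos)
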