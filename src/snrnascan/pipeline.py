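"""End-to-end orchestration: simulate -> scan -> null test -> burden -> phenotypes.

``run_pipeline`` executes the whole analysis on a synthetic study generated
from one seed, writing per-stage TSV/JSON/BED reports plus a manifest
(package version, seed, configuration hash) sufficient to reproduce the
run. Individual stages are importable functions; the command-line interface
in :mod:`snrnascan.cli` exposes them over files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import (
    ContingencyTable,
    fisher_exact,
    recurrent_dnv_screen,
    snrna_burden_screen,
)
from .constraint import (
    PopulationVariantTable,
    call_depleted_regions,
    normalise_profile,
    regions_to_bed,
    regions_to_tsv,
    sliding_window_profile,
)
from .null_model import build_intergenic_pool, fisher_pitman_mc, region_summary, sample_regions
from .phenotypes import build_phenotype_counts, collapse_terms, enrich_phenotypes
from .simulate import (
    DEFAULT_TERM_MAP,
    SimulatedCohorts,
    SimulationConfig,
    simulate_cohorts,
    simulate_intergenic_population,
    write_cohorts,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the published analysis settings."""

    window_size: int = 18
    depletion_threshold: float = 0.2
    null_region_count: int = 1000
    null_region_length: int = 141
    transcript_buffer: int = 10_000
    n_permutations: int = 1000
    min_case_dnvs: int = 2
    min_ac: int = 3
    max_pop_af: float = 0.005
    alpha: float = 0.05
    min_phenotype_carriers: int = 5
    prior_diagnostic_rate: float = 0.4
    seed: int = 0
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    def validate(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        min_gene = min(g.length for g in self.simulation.genes)
        if self.window_size > min_gene:
            raise ValueError(
                f"window_size ({self.window_size}) exceeds shortest gene ({min_gene} bp)"
            )
        if not 0 < self.depletion_threshold:
            raise ValueError("depletion_threshold must be > 0")
        if self.null_region_length < self.window_size:
            raise ValueError("null_region_length must be >= window_size")
        if not 0 <= self.prior_diagnostic_rate < 1:
            raise ValueError("prior_diagnostic_rate must be in [0, 1)")
        if self.n_permutations < 1 or self.null_region_count < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("simulation", None)  # simulation derives from seed
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        sim = out.pop("simulation")
        sim.pop("genes", None)
        out["simulation"] = sim
        return out


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path, resume: bool = False) -> dict:
    """Run every stage on a synthetic study; returns the report summary.

    With ``resume=True`` an existing simulated-inputs directory is loaded
    back instead of regenerated; all downstream stages are recomputed from
    it (they are deterministic in the seed, so a resumed run reproduces a
    fresh one exactly).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    # -- stage: simulate -----------------------------------------------------
    simdir = outdir / "simulated"
    truth_path = simdir / "truth.json"
    if resume and truth_path.exists():
        logger.info("resume: loading simulated inputs from %s", simdir)
        cohorts = _load_cohorts(simdir, sim)
    else:
        cohorts = simulate_cohorts(sim)
        write_cohorts(cohorts, simdir)

    # -- stage: constraint scan ----------------------------------------------
    scandir = outdir / "scan"
    scandir.mkdir(exist_ok=True)
    profiles = {}
    regions = []
    for gene in sim.genes:
        profile = normalise_profile(
            sliding_window_profile(gene, cohorts.population, window_size=config.window_size)
        )
        profiles[gene.gene_id] = profile
        regions.extend(
            call_depleted_regions(profile, gene, threshold=config.depletion_threshold)
        )
    pd.concat(
        [p.windows.assign(gene_id=gid) for gid, p in profiles.items()], ignore_index=True
    ).to_csv(scandir / "window_profiles.tsv", sep="\t", index=False, float_format="%.6g")
    regions_to_tsv(regions, scandir / "depleted_regions.tsv")
    regions_to_bed(
        regions, {g.gene_id: g.chromosome for g in sim.genes}, scandir / "depleted_regions.bed"
    )

    # -- stage: intergenic null test ------------------------------------------
    nulldir = outdir / "null"
    nulldir.mkdir(exist_ok=True)
    focal = sim.focal_gene
    pool = build_intergenic_pool(
        [(g.start, g.end) for g in sim.genes],
        chromosome=focal.chromosome,
        chromosome_length=sim.chromosome_length,
        buffer_bp=config.transcript_buffer,
        min_len=config.null_region_length,
    )
    pool.to_bed(nulldir / "intergenic_pool.bed")
    null_regions = sample_regions(
        pool, n=config.null_region_count, length=config.null_region_length, seed=config.seed
    )
    null_regions.to_bed(nulldir / "null_regions.bed")
    null_rng = np.random.default_rng((config.seed, 4))
    intergenic_pop = simulate_intergenic_population(
        null_regions, sim.intergenic_q, sim.population_size, null_rng
    )
    gene_summaries = [
        region_summary(g, cohorts.population, window_size=config.window_size)
        for g in (sim.focal_gene, *[g for g in sim.genes if g.gene_id == "U4L-1"])
    ]
    null_summaries = [
        region_summary(r, intergenic_pop, window_size=config.window_size, chromosome=null_regions.chromosome)
        for r in null_regions.regions
    ]
    perm = fisher_pitman_mc(
        gene_summaries,
        null_summaries,
        n_permutations=config.n_permutations,
        alternative="greater",
        seed=config.seed,
    )
    (nulldir / "permutation_test.json").write_text(
        json.dumps(
            {
                **perm.to_dict(),
                "gene_summaries": gene_summaries,
                "null_summary_mean": float(np.mean(null_summaries)),
            },
            indent=2,
        )
        + "\n"
    )

    # -- stage: burden --------------------------------------------------------
    burdendir = outdir / "burden"
    burdendir.mkdir(exist_ok=True)
    unit_counts = _dnv_carrier_counts(cohorts, sim, regions)
    screen = snrna_burden_screen(
        unit_counts,
        n_case_probands=sim.n_case,
        n_control_probands=sim.n_control,
        min_case_dnvs=config.min_case_dnvs,
        alpha=config.alpha,
    )
    screen.results.to_csv(burdendir / "dnv_screen.tsv", sep="\t", index=False, float_format="%.6g")
    lo, hi = sim.constrained_region
    case_in = _region_carriers(cohorts.case_dnvs, focal, lo, hi)
    ctrl_in = _region_carriers(cohorts.control_dnvs, focal, lo, hi)
    table = ContingencyTable.from_carriers(case_in, sim.n_case, ctrl_in, sim.n_control)
    res = fisher_exact(table)
    (burdendir / "critical_region_2x2.json").write_text(
        json.dumps(
            {
                "case_carriers": case_in,
                "n_case": sim.n_case,
                "control_carriers": ctrl_in,
                "n_control": sim.n_control,
                **res.to_dict(),
                "n_tests": screen.n_tests,
                "alpha_bonferroni": screen.alpha_bonferroni,
            },
            indent=2,
        )
        + "\n"
    )
    recurrent = recurrent_dnv_screen(
        _variant_counts(cohorts.case_dnvs),
        {"control": _variant_counts(cohorts.control_dnvs)},
        _population_afs(cohorts.population),
        min_ac=config.min_ac,
        max_pop_af=config.max_pop_af,
    )
    recurrent.to_csv(burdendir / "recurrent_dnvs.tsv", sep="\t", index=False, float_format="%.6g")

    # -- stage: phenotypes ------------------------------------------------------
    phenodir = outdir / "phenotypes"
    phenodir.mkdir(exist_ok=True)
    groups_by_proband = collapse_terms(cohorts.phenotype_terms, DEFAULT_TERM_MAP)
    all_case_ids = [f"case_{i:06d}" for i in range(sim.n_case)]
    comparators = [p for p in all_case_ids if p not in set(cohorts.carrier_ids)]
    counts = build_phenotype_counts(groups_by_proband, cohorts.carrier_ids, comparators)
    enrichment = enrich_phenotypes(
        counts, min_carriers=config.min_phenotype_carriers, alpha=config.alpha
    )
    enrichment.to_csv(phenodir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "package": "snrnascan",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": ["simulate", "scan", "null", "burden", "phenotypes"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "manifest": manifest,
        "depleted_regions": regions,
        "permutation": perm,
        "screen": screen,
        "critical_region": res,
        "recurrent": recurrent,
        "phenotype_enrichment": enrichment,
    }


def _load_cohorts(simdir: Path, sim: SimulationConfig) -> SimulatedCohorts:
    population = PopulationVariantTable.from_vcf(simdir / "population.vcf", cohort_size=sim.population_size)
    case = pd.read_csv(simdir / "case_dnvs.tsv", sep="\t")
    control = pd.read_csv(simdir / "control_dnvs.tsv", sep="\t")
    phenotypes = pd.read_csv(simdir / "phenotype_terms.tsv", sep="\t")
    carriers = (simdir / "carriers.txt").read_text().split()
    truth = json.loads((simdir / "truth.json").read_text())
    return SimulatedCohorts(population, case, control, phenotypes, carriers, truth)


def _region_carriers(dnvs: pd.DataFrame, gene, n_lo: int, n_hi: int) -> int:
    g_bounds = sorted((gene.genomic_position(n_lo), gene.genomic_position(n_hi)))
    mask = (
        (dnvs["gene_id"] == gene.gene_id)
        & (dnvs["position"] >= g_bounds[0])
        & (dnvs["position"] <= g_bounds[1])
    )
    return int(dnvs.loc[mask, "proband_id"].nunique())


def _dnv_carrier_counts(cohorts: SimulatedCohorts, sim: SimulationConfig, regions) -> pd.DataFrame:
    rows = []
    for gene in sim.genes:
        case = int(cohorts.case_dnvs.loc[cohorts.case_dnvs["gene_id"] == gene.gene_id, "proband_id"].nunique())
        ctrl = int(cohorts.control_dnvs.loc[cohorts.control_dnvs["gene_id"] == gene.gene_id, "proband_id"].nunique())
        rows.append({"unit": gene.gene_id, "case_carriers": case, "control_carriers": ctrl})
    gene_by_id = {g.gene_id: g for g in sim.genes}
    for region in regions:
        gene = gene_by_id[region.gene_id]
        rows.append(
            {
                "unit": f"{region.gene_id}:n.{region.n_start}-{region.n_end}",
                "case_carriers": _region_carriers(cohorts.case_dnvs, gene, region.n_start, region.n_end),
                "control_carriers": _region_carriers(cohorts.control_dnvs, gene, region.n_start, region.n_end),
            }
        )
    return pd.DataFrame(rows, columns=["unit", "case_carriers", "control_carriers"])


def _variant_counts(dnvs: pd.DataFrame) -> dict[tuple, int]:
    counts = dnvs.groupby(["chromosome", "position", "ref", "alt"]).size()
    return {key: int(v) for key, v in counts.items()}


def _population_afs(pop: PopulationVariantTable) -> dict[tuple, float]:
    df = pop.df
    return {
        (r.chromosome, r.position, r.ref, r.alt): r.ac / r.an
        for r in df.itertuples(index=False)
    }
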