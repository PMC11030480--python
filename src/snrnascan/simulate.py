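"""Synthetic cohorts with the statistical structure the analyses assume.

The real inputs behind this kind of study — national-cohort variant tables,
half-million-genome population callsets, trio de novo callsets, phenotype
registries — are access-controlled. This module generates stand-ins with
the documented statistical structure so every pipeline stage runs and is
testable end to end:

* a population variant table in which each possible SNV of a gene is
  observed independently, with probability ``q_out`` (default 0.78)
  outside a planted constrained region and ``q_in`` (default 0.26) inside
  it, allele counts following a truncated geometric tail capped at a
  maximum allele frequency (default 0.025%);
* case/control de novo variant tables where case probands draw variants at
  an elevated rate inside the constrained region (enrichment ``rho``), a
  fixed fraction of in-region case variants being one recurrent single-base
  insertion (default 77.3%);
* phenotype-term tables where carriers show elevated odds for a configurable
  set of phenotype groups.

The bundled U4-like loci are *synthetic*: coordinates and strand match the
published locus description, but the 141-nt sequences are pseudo-random,
with the handful of transcript positions that appear in the documented
variant-nomenclature examples fixed so those examples hold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constraint import PopulationVariantTable
from .gene_model import (
    NUCLEOTIDES,
    GeneLocus,
    GenomicVariant,
    TranscriptInterval,
    complement,
    enumerate_possible_snvs,
    genomic_to_transcript,
)
from .null_model import RandomRegionSet

DNV_COLUMNS = ["proband_id", "gene_id", "chromosome", "position", "ref", "alt", "n_description"]

# transcript bases fixed so documented n. nomenclature examples are valid
_FIXED_TRANSCRIPT_BASES = {63: "T", 65: "A", 66: "A", 67: "A", 69: "C", 76: "C", 77: "A", 78: "A"}

#: phenotype group -> (baseline probability among comparator probands, carrier odds ratio)
DEFAULT_PHENOTYPE_GROUPS: dict[str, tuple[float, float]] = {
    "global developmental delay": (0.54, 3.56),
    "microcephaly": (0.16, 6.62),
    "hypotonia": (0.15, 3.60),
    "drooling": (0.009, 19.2),
}

#: raw ontology codes collapsed into each group (explicit list, no graph closure)
DEFAULT_TERM_MAP: dict[str, str] = {
    "HP:0001263": "global developmental delay",
    "HP:0012736": "global developmental delay",
    "R62": "global developmental delay",
    "HP:0000252": "microcephaly",
    "HP:0001252": "hypotonia",
    "HP:0001290": "hypotonia",
    "HP:0002307": "drooling",
}


def _synthetic_sequence(length: int, seed: int, fixed: dict[int, str] | None = None) -> str:
    rng = np.random.default_rng(seed)
    bases = list("".join(rng.choice(list(NUCLEOTIDES), size=length)))
    for n, base in (fixed or {}).items():
        bases[n - 1] = base
    return "".join(bases)


def u4_like_gene() -> GeneLocus:
    """The focal 141-bp minus-strand U4-like locus (synthetic sequence)."""
    return GeneLocus(
        gene_id="U4L-2",
        chromosome="chr12",
        strand="-",
        start=120_291_763,
        end=120_291_903,
        sequence=_synthetic_sequence(141, seed=420_002, fixed=_FIXED_TRANSCRIPT_BASES),
        name="U4L-2",
        biotype="snRNA",
    )


def u4_paralog_gene() -> GeneLocus:
    """A contiguous 141-bp paralog differing from the focal gene at 4 nt."""
    focal = u4_like_gene()
    seq = list(focal.sequence)
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for n in (10, 40, 100, 130):  # exactly four substitutions -> 97.2% identity
        seq[n - 1] = swap[seq[n - 1]]
    return GeneLocus(
        gene_id="U4L-1",
        chromosome="chr12",
        strand="-",
        start=120_290_647,
        end=120_290_787,
        sequence="".join(seq),
        name="U4L-1",
        biotype="snRNA",
    )


def decoy_genes(n: int = 3, length: int = 141, seed: int = 77) -> list[GeneLocus]:
    """Unconstrained snRNA-like decoys spread along the chromosome."""
    genes = []
    for i in range(n):
        start = 40_000_000 + i * 5_000_000
        genes.append(
            GeneLocus(
                gene_id=f"SNDECOY-{i + 1}",
                chromosome="chr12",
                strand="+" if i % 2 == 0 else "-",
                start=start,
                end=start + length - 1,
                sequence=_synthetic_sequence(length, seed=seed + i),
                name=f"SNDECOY-{i + 1}",
                biotype="snRNA",
            )
        )
    return genes


def _default_genes() -> tuple[GeneLocus, ...]:
    return (u4_like_gene(), u4_paralog_gene(), *decoy_genes())


@dataclass
class SimulationConfig:
    """All generative parameters for the synthetic cohorts.

    Defaults are the documented study conditions: per-possible-SNV
    observation probabilities 0.78 outside / 0.26 inside the planted
    constrained region (transcript nucleotides 62-79 of the focal gene),
    allele frequencies capped at 0.025%, a population of 490,640
    individuals, trio-arm sizes of 5,426 undiagnosed-NDD and 4,776 non-NDD
    probands, a recurrent insertion carrying 77.3% of in-region case
    variants, and an intergenic per-SNV observation probability of 0.13.
    ``dnv_rate`` (de novo variants per proband per gene) and the in-region
    case enrichment ``region_enrichment`` are set so a 141-bp gene collects
    a handful of baseline de novo variants per cohort and the focal region
    roughly 35 case variants, the reported order of magnitude.
    """

    genes: tuple[GeneLocus, ...] = field(default_factory=_default_genes)
    focal_gene_id: str = "U4L-2"
    constrained_region: tuple[int, int] = (62, 79)
    q_out: float = 0.78
    q_in: float = 0.26
    af_max: float = 2.5e-4
    ac_geometric_p: float = 0.1
    population_size: int = 490_640
    n_case: int = 5_426
    n_control: int = 4_776
    dnv_rate: float = 5e-4
    region_enrichment: float = 100.0
    insertion_weight: float = 0.773
    intergenic_q: float = 0.13
    chromosome_length: int = 133_275_309
    phenotype_groups: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_GROUPS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_out", "q_in", "insertion_weight", "intergenic_q"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.region_enrichment < 0:
            raise ValueError("region_enrichment must be >= 0")
        if min(self.n_case, self.n_control, self.population_size) < 0:
            raise ValueError("cohort sizes must be >= 0")
        for _, (p0, orr) in self.phenotype_groups.items():
            if not 0 < p0 < 1:
                raise ValueError("phenotype baseline probabilities must be in (0, 1)")
            if orr <= 0:
                raise ValueError("phenotype odds ratios must be > 0")

    @property
    def focal_gene(self) -> GeneLocus:
        for gene in self.genes:
            if gene.gene_id == self.focal_gene_id:
                return gene
        raise ValueError(f"focal gene {self.focal_gene_id!r} not among configured genes")

    @property
    def hotspot(self) -> GenomicVariant:
        """The recurrent single-base insertion at n.64_65 of the focal gene."""
        gene = self.focal_gene
        g = gene.genomic_position(65)  # plus-strand anchor of the n.64_65 bond
        anchor = gene.plus_strand_base(g)
        inserted = complement("T")  # transcript-strand insT -> plus-strand A
        return GenomicVariant(gene.chromosome, g, anchor, anchor + inserted)

    def truth(self) -> dict:
        gene = self.focal_gene
        lo, hi = self.constrained_region
        return {
            "focal_gene_id": self.focal_gene_id,
            "constrained_region_n": [lo, hi],
            "constrained_region_genomic": sorted(
                (gene.genomic_position(lo), gene.genomic_position(hi))
            ),
            "q_out": self.q_out,
            "q_in": self.q_in,
            "af_max": self.af_max,
            "population_size": self.population_size,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "dnv_rate": self.dnv_rate,
            "region_enrichment": self.region_enrichment,
            "insertion_weight": self.insertion_weight,
            "hotspot": str(self.hotspot),
            "intergenic_q": self.intergenic_q,
            "phenotype_groups": {
                g: {"p0": p0, "odds_ratio": orr} for g, (p0, orr) in self.phenotype_groups.items()
            },
            "seed": self.seed,
        }


@dataclass
class SimulatedCohorts:
    population: PopulationVariantTable
    case_dnvs: pd.DataFrame
    control_dnvs: pd.DataFrame
    phenotype_terms: pd.DataFrame
    carrier_ids: list[str]
    truth: dict


def _draw_allele_counts(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    an = 2 * config.population_size
    ac_max = max(1, int(config.af_max * an))
    ac = rng.geometric(config.ac_geometric_p, size=n)
    return np.minimum(ac, ac_max)


def _in_region(config: SimulationConfig, gene: GeneLocus, n_position: int) -> bool:
    lo, hi = config.constrained_region
    return gene.gene_id == config.focal_gene_id and lo <= n_position <= hi


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PopulationVariantTable:
    """Population variant table over all configured genes.

    Every possible SNV of every gene is observed independently with
    probability ``q_in`` inside the focal gene's constrained region and
    ``q_out`` elsewhere; observed variants receive allele counts from a
    geometric tail truncated at ``af_max``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    an = 2 * config.population_size
    records = []
    for gene in config.genes:
        for variant in enumerate_possible_snvs(gene):
            n_pos = gene.transcript_position(variant.position)
            q = config.q_in if _in_region(config, gene, n_pos) else config.q_out
            if rng.random() < q:
                records.append(variant)
    acs = _draw_allele_counts(rng, len(records), config)
    return PopulationVariantTable.from_records(
        [(v, int(ac), an) for v, ac in zip(records, acs)],
        cohort_size=config.population_size,
    )


def _random_snv(gene: GeneLocus, n_position: int, rng: np.random.Generator) -> GenomicVariant:
    g = gene.genomic_position(n_position)
    ref = gene.plus_strand_base(g)
    alts = [b for b in NUCLEOTIDES if b != ref]
    return GenomicVariant(gene.chromosome, g, ref, alts[int(rng.integers(0, 3))])


def simulate_denovo_cohorts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-proband de novo variant tables for case and control arms.

    Control probands draw variants uniformly over gene positions at
    ``dnv_rate`` per proband per gene; case probands draw at ``dnv_rate``
    outside the focal constrained region and ``dnv_rate x region_enrichment``
    inside it, a fraction ``insertion_weight`` of in-region case variants
    being the fixed hotspot insertion.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if config.seed is not None else None)
    lo, hi = config.constrained_region
    hotspot = config.hotspot

    def draw_arm(n_probands: int, prefix: str, enriched: bool) -> pd.DataFrame:
        rows = []
        for gene in config.genes:
            L = gene.length
            per_pos = config.dnv_rate / L
            is_focal = gene.gene_id == config.focal_gene_id
            region_positions = list(range(lo, hi + 1)) if is_focal else []
            out_positions = [n for n in range(1, L + 1) if n not in set(region_positions)]

            def emit(n_events: int, positions: list[int], allow_hotspot: bool):
                for _ in range(n_events):
                    proband = f"{prefix}{int(rng.integers(0, n_probands)):06d}"
                    if allow_hotspot and rng.random() < config.insertion_weight:
                        v = hotspot
                    else:
                        n_pos = positions[int(rng.integers(0, len(positions)))]
                        v = _random_snv(gene, n_pos, rng)
                    rows.append(
                        {
                            "proband_id": proband,
                            "gene_id": gene.gene_id,
                            "chromosome": v.chromosome,
                            "position": v.position,
                            "ref": v.ref,
                            "alt": v.alt,
                            "n_description": genomic_to_transcript(gene, v).n_description,
                        }
                    )

            n_out = rng.poisson(n_probands * per_pos * len(out_positions))
            emit(int(n_out), out_positions, allow_hotspot=False)
            if region_positions:
                rate = per_pos * (config.region_enrichment if enriched else 1.0)
                n_in = rng.poisson(n_probands * rate * len(region_positions))
                emit(int(n_in), region_positions, allow_hotspot=enriched)
        df = pd.DataFrame(rows, columns=DNV_COLUMNS)
        return df.sort_values(["gene_id", "position", "proband_id"]).reset_index(drop=True)

    case = draw_arm(config.n_case, "case_", enriched=True)
    control = draw_arm(config.n_control, "ctrl_", enriched=False)
    return case, control


def solve_carrier_probability(p0: float, odds_ratio: float) -> float:
    """p1 with odds(p1) = OR x odds(p0)."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    o1 = odds_ratio * p0 / (1 - p0)
    return o1 / (1 + o1)


def simulate_phenotypes(
    carrier_ids,
    noncarrier_ids,
    groups: dict[str, tuple[float, float]] | None = None,
    term_map: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format phenotype term table (proband_id, code).

    Non-carriers show each group with its baseline probability p0; carriers
    with p1 such that odds(p1) = OR x odds(p0). Each expressed group is
    recorded as one of its raw ontology codes (uniformly chosen), so the
    collapsing step has real work to do.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    groups = DEFAULT_PHENOTYPE_GROUPS if groups is None else groups
    term_map = DEFAULT_TERM_MAP if term_map is None else term_map
    codes_by_group: dict[str, list[str]] = {}
    for code, group in term_map.items():
        codes_by_group.setdefault(group, []).append(code)
    rows = []
    for ids, is_carrier in ((list(carrier_ids), True), (list(noncarrier_ids), False)):
        for proband in ids:
            for group, (p0, orr) in groups.items():
                p = solve_carrier_probability(p0, orr) if is_carrier else p0
                if rng.random() < p:
                    codes = codes_by_group.get(group, [group])
                    rows.append(
                        {"proband_id": proband, "code": codes[int(rng.integers(0, len(codes)))]}
                    )
    return pd.DataFrame(rows, columns=["proband_id", "code"])


def simulate_intergenic_population(
    regions: RandomRegionSet,
    q: float,
    population_size: int,
    rng: np.random.Generator,
    ac_geometric_p: float = 0.1,
    af_max: float = 2.5e-4,
) -> PopulationVariantTable:
    """Population variants over null regions: each possible SNV with prob q.

    Null regions have no curated reference sequence; a pseudo-random
    reference base is drawn per position and each of its three alternates is
    observed independently with probability q.
    """
    an = 2 * population_size
    ac_max = max(1, int(af_max * an))
    rows = []
    for g_start, g_end in regions.regions:
        length = g_end - g_start + 1
        refs = rng.choice(list(NUCLEOTIDES), size=length)
        observed = rng.random((length, 3)) < q
        for i in range(length):
            alts = [b for b in NUCLEOTIDES if b != refs[i]]
            for j in range(3):
                if observed[i, j]:
                    rows.append(
                        {
                            "chromosome": regions.chromosome,
                            "position": g_start + i,
                            "ref": refs[i],
                            "alt": alts[j],
                            "ac": int(min(rng.geometric(ac_geometric_p), ac_max)),
                            "an": an,
                        }
                    )
    df = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt", "ac", "an"])
    return PopulationVariantTable(df, cohort_size=population_size)


def simulate_cohorts(config: SimulationConfig) -> SimulatedCohorts:
    """Full synthetic study: population, de novo arms, phenotypes, truth.

    Deterministic for a fixed config: all randomness flows from
    ``config.seed`` through independent, purpose-keyed generators.
    """
    pop = simulate_population(config, np.random.default_rng((config.seed, 1)))
    case, control = simulate_denovo_cohorts(config, np.random.default_rng((config.seed, 2)))
    hotspot = config.hotspot
    carrier_ids = sorted(
        set(
            case.loc[
                (case["position"] == hotspot.position)
                & (case["ref"] == hotspot.ref)
                & (case["alt"] == hotspot.alt),
                "proband_id",
            ]
        )
    )
    all_case_ids = [f"case_{i:06d}" for i in range(config.n_case)]
    noncarriers = [p for p in all_case_ids if p not in set(carrier_ids)]
    phenotypes = simulate_phenotypes(
        carrier_ids,
        noncarriers,
        groups=config.phenotype_groups,
        rng=np.random.default_rng((config.seed, 3)),
    )
    return SimulatedCohorts(
        population=pop,
        case_dnvs=case,
        control_dnvs=control,
        phenotype_terms=phenotypes,
        carrier_ids=carrier_ids,
        truth=config.truth(),
    )


def write_cohorts(cohorts: SimulatedCohorts, outdir: str | Path) -> dict[str, Path]:
    """Emit VCF + TSV + truth JSON; byte-identical for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "population_vcf": outdir / "population.vcf",
        "case_dnvs": outdir / "case_dnvs.tsv",
        "control_dnvs": outdir / "control_dnvs.tsv",
        "phenotype_terms": outdir / "phenotype_terms.tsv",
        "carriers": outdir / "carriers.txt",
        "truth": outdir / "truth.json",
    }
    cohorts.population.to_vcf(paths["population_vcf"])
    cohorts.case_dnvs.to_csv(paths["case_dnvs"], sep="\t", index=False)
    cohorts.control_dnvs.to_csv(paths["control_dnvs"], sep="\t", index=False)
    cohorts.phenotype_terms.to_csv(paths["phenotype_terms"], sep="\t", index=False)
    paths["carriers"].write_text("".join(f"{p}\n" for p in cohorts.carrier_ids))
    paths["truth"].write_text(json.dumps(cohorts.truth, indent=2, sort_keys=True) + "\n")
    return paths
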