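"""Sliding-window constraint scan over small genes.

The scan asks, for every 18-bp window of a gene, what fraction of the 54
possible single-nucleotide substitutions is actually observed as standing
variation in a large population cohort. Windows are normalised by
subtracting the per-gene median fraction, and runs of windows at least 20
percentage points below the median are called depleted (constrained)
regions. The approach deliberately avoids sequence-context mutation-rate
models: snRNA loci are hypermutable enough that the gene acts as its own
calibration, and depletion relative to the rest of the same gene is the
signal of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_model import (
    GeneLocus,
    GenomicVariant,
    OutOfLocusError,
    TranscriptInterval,
    enumerate_possible_snvs,
    transcript_region_to_genomic,
)

logger = logging.getLogger(__name__)

POP_COLUMNS = ["chromosome", "position", "ref", "alt", "ac", "an"]


@dataclass
class PopulationVariantTable:
    """Observed variants with allele counts over a population cohort.

    ``df`` columns: chromosome, position (1-based), ref, alt, ac (allele
    count, >= 1), an (allele number). ``cohort_size`` is the number of
    sequenced individuals the table summarises.
    """

    df: pd.DataFrame
    cohort_size: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in POP_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"population table missing columns {missing}")
        df = self.df
        if (df["ac"] < 1).any():
            raise ValueError("allele counts must be >= 1")
        if (df["ac"] > df["an"]).any():
            raise ValueError("allele count exceeds allele number")
        keys = df[["chromosome", "position", "ref", "alt"]]
        if keys.duplicated().any():
            raise ValueError("duplicate variant records")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records, cohort_size: int | None = None) -> "PopulationVariantTable":
        """Build from (GenomicVariant, ac, an) triples."""
        rows = [
            {
                "chromosome": v.chromosome,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "ac": ac,
                "an": an,
            }
            for v, ac, an in records
        ]
        df = pd.DataFrame(rows, columns=POP_COLUMNS)
        return cls(df, cohort_size=cohort_size)

    @classmethod
    def from_tsv(cls, path: str | Path, cohort_size: int | None = None) -> "PopulationVariantTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "ref": str, "alt": str})
        return cls(df[POP_COLUMNS], cohort_size=cohort_size)

    @classmethod
    def from_vcf(cls, path: str | Path, cohort_size: int | None = None) -> "PopulationVariantTable":
        """Read CHROM/POS/REF/ALT plus INFO AC/AN from a VCF."""
        from cyvcf2 import VCF

        rows = []
        for record in VCF(str(path)):
            acs = record.INFO.get("AC")
            an = record.INFO.get("AN")
            alts = record.ALT
            if acs is None:
                acs = [1] * len(alts)
            elif not isinstance(acs, (tuple, list)):
                acs = [acs]
            for alt, ac in zip(alts, acs):
                rows.append(
                    {
                        "chromosome": record.CHROM,
                        "position": record.POS,
                        "ref": record.REF,
                        "alt": alt,
                        "ac": int(ac),
                        "an": int(an) if an is not None else int(ac),
                    }
                )
        return cls(pd.DataFrame(rows, columns=POP_COLUMNS), cohort_size=cohort_size)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with AC/AN INFO fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
            fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
            for chrom in pd.unique(self.df["chromosome"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            ordered = self.df.sort_values(["chromosome", "position", "ref", "alt"])
            for row in ordered.itertuples(index=False):
                fh.write(
                    f"{row.chromosome}\t{row.position}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                    f"AC={row.ac};AN={row.an}\n"
                )

    def snvs_in(self, chromosome: str, g_start: int, g_end: int) -> pd.DataFrame:
        df = self.df
        mask = (
            (df["chromosome"] == chromosome)
            & (df["position"] >= g_start)
            & (df["position"] <= g_end)
            & (df["ref"].str.len() == 1)
            & (df["alt"].str.len() == 1)
        )
        return df[mask]

    def max_allele_frequency(self) -> float:
        if len(self.df) == 0:
            return 0.0
        return float((self.df["ac"] / self.df["an"]).max())


@dataclass
class WindowProfile:
    """Per-window observed/possible SNV proportions across one gene.

    ``windows`` columns: offset (transcript position of window start),
    g_start/g_end (genomic extent), proportion (observed / possible, in
    [0, 1]) and, after :func:`normalise_profile`, normalised (proportion
    minus the per-gene median proportion).
    """

    gene_id: str
    window_size: int
    step: int
    windows: pd.DataFrame

    @property
    def is_normalised(self) -> bool:
        return "normalised" in self.windows.columns

    def to_tsv(self, path: str | Path) -> None:
        out = self.windows.copy()
        out.insert(0, "gene_id", self.gene_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class DepletedRegion:
    """A called constrained region: a run of depleted windows.

    ``n_start``/``n_end`` give the union extent of the qualifying windows in
    transcript coordinates and ``g_start``/``g_end`` the matching genomic
    span. ``core_n_start``/``core_n_end`` record the single most-depleted
    window (ties broken 5'-most), the best point estimate of where the
    constrained element sits; the union extent is systematically wider than
    the underlying element because every window overlapping it enough
    qualifies.
    """

    gene_id: str
    n_start: int
    n_end: int
    g_start: int
    g_end: int
    min_normalised: float
    n_windows: int
    core_n_start: int
    core_n_end: int

    @property
    def transcript_interval(self) -> TranscriptInterval:
        return TranscriptInterval(self.gene_id, self.n_start, self.n_end)


def observed_proportion(
    gene: GeneLocus,
    pop: PopulationVariantTable,
    g_start: int | None = None,
    g_end: int | None = None,
) -> float:
    """Fraction of possible SNVs in the interval observed in the population.

    The numerator counts distinct possible substitutions present in the
    table (indels are ignored; a multi-allelic site contributes one unit per
    distinct alternate allele); the denominator is 3 x interval length.
    """
    g_start = gene.start if g_start is None else g_start
    g_end = gene.end if g_end is None else g_end
    possible = {v.key for v in enumerate_possible_snvs(gene, g_start, g_end)}
    observed = {
        (row.chromosome, row.position, row.ref, row.alt)
        for row in pop.snvs_in(gene.chromosome, g_start, g_end).itertuples(index=False)
    }
    return len(possible & observed) / (3 * (g_end - g_start + 1))


def _per_position_counts(gene: GeneLocus, pop: PopulationVariantTable) -> np.ndarray:
    """Distinct observed possible-SNV count (0..3) per transcript position."""
    counts = np.zeros(gene.length, dtype=np.int64)
    sub = pop.snvs_in(gene.chromosome, gene.start, gene.end)
    seen: set[tuple[int, str]] = set()
    for row in sub.itertuples(index=False):
        if gene.plus_strand_base(row.position) != row.ref:
            continue  # not a possible SNV of this locus (reference mismatch)
        key = (row.position, row.alt)
        if key in seen:
            continue
        seen.add(key)
        counts[gene.transcript_position(row.position) - 1] += 1
    return counts


def sliding_window_profile(
    gene: GeneLocus,
    pop: PopulationVariantTable,
    window_size: int = 18,
    step: int = 1,
) -> WindowProfile:
    """Observed/possible SNV proportion in every sliding window of the gene.

    Windows are indexed by their transcript start offset (1..L-w+1 for
    step 1) and are always fully contained in the gene.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    if gene.length < window_size:
        raise ValueError(
            f"gene {gene.gene_id} ({gene.length} bp) shorter than window ({window_size} bp)"
        )
    counts = _per_position_counts(gene, pop)
    csum = np.concatenate([[0], np.cumsum(counts)])
    offsets = np.arange(1, gene.length - window_size + 2, step)
    observed = csum[offsets - 1 + window_size] - csum[offsets - 1]
    proportions = observed / (3.0 * window_size)
    g_bounds = [
        transcript_region_to_genomic(gene, TranscriptInterval(gene.gene_id, int(o), int(o) + window_size - 1))
        for o in offsets
    ]
    windows = pd.DataFrame(
        {
            "offset": offsets,
            "g_start": [b[0] for b in g_bounds],
            "g_end": [b[1] for b in g_bounds],
            "proportion": proportions,
        }
    )
    return WindowProfile(gene.gene_id, window_size, step, windows)


def normalise_profile(profile: WindowProfile) -> WindowProfile:
    """Subtract the per-gene median proportion from every window."""
    if len(profile.windows) == 0:
        raise ValueError("profile has no windows")
    windows = profile.windows.copy()
    windows["normalised"] = windows["proportion"] - windows["proportion"].median()
    return WindowProfile(profile.gene_id, profile.window_size, profile.step, windows)


def call_depleted_regions(
    profile: WindowProfile,
    gene: GeneLocus,
    threshold: float = 0.2,
    inclusive: bool = True,
    extent: str = "union",
) -> list[DepletedRegion]:
    """Group windows depleted by at least ``threshold`` into regions.

    A window qualifies when its normalised proportion is <= -threshold
    (strictly < when ``inclusive=False``; the inclusive reading honours the
    "at least 20%" depletion definition). Qualifying windows whose extents
    overlap or are adjacent merge into one region whose extent is the union
    of the member windows (``extent="intersection"`` instead reports the
    bases shared by all member windows, when non-empty).
    """
    if not profile.is_normalised:
        profile = normalise_profile(profile)
    if extent not in ("union", "intersection"):
        raise ValueError(f"unknown extent mode {extent!r}")
    w = profile.window_size
    df = profile.windows
    # tolerance so a window sitting exactly at the threshold (up to float
    # noise from the median subtraction) is treated as a tie
    eps = 1e-9
    if inclusive:
        qual = df[df["normalised"] <= -threshold + eps]
    else:
        qual = df[df["normalised"] < -threshold - eps]
    if len(qual) == 0:
        return []

    regions: list[DepletedRegion] = []
    group: list[pd.Series] = []

    def flush(group):
        offsets = np.array([int(r.offset) for r in group])
        values = np.array([float(r.normalised) for r in group])
        if extent == "union":
            n_start, n_end = int(offsets.min()), int(offsets.max()) + w - 1
        else:
            n_start, n_end = int(offsets.max()), int(offsets.min()) + w - 1
            if n_start > n_end:
                logger.warning(
                    "%s: intersection extent empty for group at offsets %d..%d; skipped",
                    profile.gene_id, offsets.min(), offsets.max(),
                )
                return
        core_offset = int(offsets[values.argmin()])
        g_start, g_end = transcript_region_to_genomic(
            gene, TranscriptInterval(gene.gene_id, n_start, n_end)
        )
        regions.append(
            DepletedRegion(
                gene_id=profile.gene_id,
                n_start=n_start,
                n_end=n_end,
                g_start=g_start,
                g_end=g_end,
                min_normalised=float(values.min()),
                n_windows=len(group),
                core_n_start=core_offset,
                core_n_end=core_offset + w - 1,
            )
        )

    prev_end = None
    for row in qual.itertuples(index=False):
        start, end = int(row.offset), int(row.offset) + w - 1
        if prev_end is not None and start > prev_end + 1:
            flush(group)
            group = []
        group.append(row)
        prev_end = end if prev_end is None else max(prev_end, end)
    flush(group)
    return regions


def min_normalised(profile: WindowProfile, n_start: int, n_end: int) -> float:
    """Minimum normalised value among windows overlapping [n_start, n_end]."""
    if not profile.is_normalised:
        profile = normalise_profile(profile)
    w = profile.window_size
    df = profile.windows
    overlap = df[(df["offset"] <= n_end) & (df["offset"] + w - 1 >= n_start)]
    if len(overlap) == 0:
        raise ValueError(f"no window overlaps n.{n_start}-{n_end}")
    return float(overlap["normalised"].min())


def regions_to_bed(regions: list[DepletedRegion], chromosome_of: dict[str, str], path: str | Path) -> None:
    """Write depleted regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            chrom = chromosome_of[r.gene_id]
            fh.write(
                f"{chrom}\t{r.g_start - 1}\t{r.g_end}\t{r.gene_id}:n.{r.n_start}-{r.n_end}\t"
                f"{r.min_normalised:.4f}\t.\n"
            )


def regions_to_tsv(regions: list[DepletedRegion], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "n_start": r.n_start,
            "n_end": r.n_end,
            "g_start": r.g_start,
            "g_end": r.g_end,
            "min_normalised": r.min_normalised,
            "n_windows": r.n_windows,
            "core_n_start": r.core_n_start,
            "core_n_end": r.core_n_end,
        }
        for r in regions
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_start", "n_end", "g_start", "g_end",
            "min_normalised", "n_windows", "core_n_start", "core_n_end",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
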