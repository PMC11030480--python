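"""Exact 2x2 association statistics and burden/recurrence screens.

The central tool is Fisher's exact test with the *conditional maximum
likelihood* odds ratio: conditioning on both margins of a 2x2 table, the
count in the top-left cell follows Fisher's noncentral hypergeometric
distribution with noncentrality equal to the odds ratio; the reported
estimate maximises that conditional likelihood and the confidence interval
inverts its exact tails. This is the convention of ``fisher.test`` in R —
the one under which published odds ratios in human genetics are computed —
and differs from the sample cross-product ratio ``ad/bc`` (also reported,
as a secondary field). Root finding deliberately mirrors R's ``uniroot``
scheme (Brent's zeroin on a reciprocal-bracketed scale with R's default
tolerance) so that estimates agree with R to the digits R itself resolves;
pass ``tol=1e-12`` for maximum-precision roots instead.

Degenerate tables are handled the way the conditional framework dictates:
an observed count at the support boundary yields an estimate of 0 or
infinity and one-sided confidence bounds, never an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

_EPS = float(np.finfo(float).eps)
_R_TOL = _EPS ** 0.25  # R uniroot default tolerance
_REL_ERR = 1 + 1e-7    # R fisher.test two-sided tie tolerance


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are cohorts, columns carrier / non-carrier."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("all-zero table")

    @classmethod
    def from_carriers(cls, carriers_1: int, total_1: int, carriers_2: int, total_2: int):
        """Carriers-among-cohort layout: non-carrier cells are total - carriers."""
        return cls(carriers_1, total_1 - carriers_1, carriers_2, total_2 - carriers_2)

    @property
    def cross_product_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def swap_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class ExactTestResult:
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    sample_odds_ratio: float
    confidence: float = 0.95
    method: str = "fisher-exact-conditional-mle"

    def to_dict(self) -> dict:
        def _num(x):
            return "inf" if math.isinf(x) else x
        return {
            "p_value": self.p_value,
            "odds_ratio": _num(self.odds_ratio),
            "ci_low": _num(self.ci_low),
            "ci_high": _num(self.ci_high),
            "sample_odds_ratio": _num(self.sample_odds_ratio),
            "confidence": self.confidence,
            "method": self.method,
        }


def _zeroin(f, ax: float, bx: float, tol: float, maxit: int = 1000) -> float:
    """Brent's zeroin, ported from R's root finder (R_zeroin2)."""
    a, b, c = ax, bx, ax
    fa, fb = f(a), f(b)
    fc = fa
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:
        raise ValueError("root not bracketed")
    while maxit > 0:
        maxit -= 1
        prev_step = b - a
        if abs(fc) < abs(fb):
            a, b, c = b, c, b
            fa, fb, fc = fb, fc, fb
        tol_act = 2 * _EPS * abs(b) + tol / 2
        new_step = (c - b) / 2
        if abs(new_step) <= tol_act or fb == 0.0:
            return b
        if abs(prev_step) >= tol_act and abs(fa) > abs(fb):
            cb = c - b
            if a == c:
                t1 = fb / fa
                p = cb * t1
                q = 1.0 - t1
            else:
                q = fa / fc
                t1 = fb / fc
                t2 = fb / fa
                p = t2 * (cb * q * (q - t1) - (b - a) * (t1 - 1.0))
                q = (q - 1.0) * (t1 - 1.0) * (t2 - 1.0)
            if p > 0:
                q = -q
            else:
                p = -p
            if p < (0.75 * cb * q - abs(tol_act * q) / 2) and p < abs(prev_step * q / 2):
                new_step = p / q
        if abs(new_step) < tol_act:
            new_step = tol_act if new_step > 0 else -tol_act
        a, fa = b, fb
        b += new_step
        fb = f(b)
        if (fb > 0) == (fc > 0):
            c, fc = a, fa
    return b


class _ConditionalDist:
    """Fisher's noncentral hypergeometric machinery for one 2x2 table."""

    def __init__(self, table: ContingencyTable):
        m = table.a + table.c          # column-1 margin
        n = table.b + table.d          # column-2 margin
        k = table.a + table.b          # row-1 margin
        self.x = table.a
        self.lo = max(0, k - n)
        self.hi = min(k, m)
        self.support = np.arange(self.lo, self.hi + 1)
        self.logdc = hypergeom.logpmf(self.support, m + n, m, k)

    def pmf(self, psi: float) -> np.ndarray:
        d = self.logdc + math.log(psi) * self.support
        d = np.exp(d - d.max())
        return d / d.sum()

    def mean(self, psi: float) -> float:
        if psi == 0:
            return float(self.lo)
        if math.isinf(psi):
            return float(self.hi)
        return float((self.support * self.pmf(psi)).sum())

    def cdf(self, q: int, psi: float, upper: bool = False) -> float:
        if psi == 0:
            return float(self.lo > q) if upper else float(self.lo <= q)
        if math.isinf(psi):
            return float(self.hi > q) if upper else float(self.hi <= q)
        d = self.pmf(psi)
        if upper:
            return float(d[self.support > q].sum())
        return float(d[self.support <= q].sum())

    # --- R fisher.test's reciprocal-bracket root scheme -------------------
    def mle(self, tol: float = _R_TOL) -> float:
        x = self.x
        if x == self.lo:
            return 0.0
        if x == self.hi:
            return math.inf
        mu = self.mean(1.0)
        if mu > x:
            return _zeroin(lambda t: self.mean(t) - x, 0.0, 1.0, tol)
        if mu < x:
            return 1.0 / _zeroin(lambda t: self.mean(1.0 / t) - x, _EPS, 1.0, tol)
        return 1.0

    def ncp_upper(self, alpha: float, tol: float = _R_TOL) -> float:
        if self.x == self.hi:
            return math.inf
        p = lambda t: self.cdf(self.x, t)
        if p(1.0) < alpha:
            return _zeroin(lambda t: p(t) - alpha, 0.0, 1.0, tol)
        if p(1.0) > alpha:
            return 1.0 / _zeroin(lambda t: p(1.0 / t) - alpha, _EPS, 1.0, tol)
        return 1.0

    def ncp_lower(self, alpha: float, tol: float = _R_TOL) -> float:
        if self.x == self.lo:
            return 0.0
        p = lambda t: self.cdf(self.x - 1, t, upper=True)
        if p(1.0) > alpha:
            return _zeroin(lambda t: p(t) - alpha, 0.0, 1.0, tol)
        if p(1.0) < alpha:
            return 1.0 / _zeroin(lambda t: p(1.0 / t) - alpha, _EPS, 1.0, tol)
        return 1.0


def fisher_exact(
    table: ContingencyTable | Iterable[Iterable[int]],
    confidence: float = 0.95,
    alternative: str = "two-sided",
    compute_ci: bool = True,
    tol: float = _R_TOL,
) -> ExactTestResult:
    """Fisher's exact test with conditional-MLE odds ratio and exact CI.

    The two-sided p-value sums all conditional probabilities not exceeding
    the observed one (with R's 1e-7 relative tie tolerance); the confidence
    interval inverts the two one-sided exact tails at (1-confidence)/2 each.
    """
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(int(a), int(b), int(c), int(d))
    dist = _ConditionalDist(table)

    if alternative == "two-sided":
        d = dist.pmf(1.0) if dist.lo < dist.hi else np.array([1.0])
        p = float(d[d <= d[dist.x - dist.lo] * _REL_ERR].sum())
    elif alternative == "less":
        p = dist.cdf(dist.x, 1.0)
    elif alternative == "greater":
        p = dist.cdf(dist.x - 1, 1.0, upper=True)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)

    estimate = dist.mle(tol) if dist.lo < dist.hi else math.nan
    alpha = (1 - confidence) / 2
    if compute_ci and dist.lo < dist.hi:
        ci_low = dist.ncp_lower(alpha, tol)
        ci_high = dist.ncp_upper(alpha, tol)
    else:
        ci_low, ci_high = 0.0, math.inf
    return ExactTestResult(
        p_value=p,
        odds_ratio=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        sample_odds_ratio=table.cross_product_ratio,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# cohort arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCounts:
    carriers: int
    total_probands: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.total_probands:
            raise ValueError("need 0 <= carriers <= total_probands")


def carrier_fraction(carriers: int | CohortCounts, total_probands: int | None = None) -> float:
    """Percentage of probands carrying a variant (unrounded)."""
    if isinstance(carriers, CohortCounts):
        carriers, total_probands = carriers.carriers, carriers.total_probands
    if total_probands is None or total_probands <= 0:
        raise ValueError("total_probands must be positive")
    return 100.0 * carriers / total_probands


def extrapolated_prevalence(
    carriers: int, undiagnosed_total: int, prior_diagnostic_rate: float
) -> float:
    """Prevalence among all affected individuals, as a percentage.

    An undiagnosed cohort sits downstream of earlier diagnostic workflows;
    if a fraction r was already diagnosed upstream, the undiagnosed total
    represents (1-r) of the full cohort, so the full-cohort prevalence is
    carriers / (undiagnosed_total / (1 - r)).
    """
    if not 0 <= prior_diagnostic_rate < 1:
        raise ValueError("prior_diagnostic_rate must be in [0, 1)")
    return 100.0 * carriers / (undiagnosed_total / (1 - prior_diagnostic_rate))


def allele_frequency(allele_count: int, n_individuals: int, ploidy: int = 2) -> float:
    if allele_count > ploidy * n_individuals:
        raise ValueError("allele_count exceeds total alleles")
    return allele_count / (ploidy * n_individuals)


def allele_balance(ref_reads: int, alt_reads: int) -> float:
    """Fraction of reads supporting the alternate allele."""
    depth = ref_reads + alt_reads
    if depth <= 0:
        raise ValueError("zero read depth")
    return alt_reads / depth


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-unit exact tests with a Bonferroni-corrected alpha."""

    results: pd.DataFrame
    n_tests: int
    alpha: float
    alpha_bonferroni: float

    def significant_units(self) -> list[str]:
        if len(self.results) == 0:
            return []
        return list(self.results.loc[self.results["significant"], "unit"])


def snrna_burden_screen(
    counts: Mapping[str, tuple[int, int]] | pd.DataFrame,
    n_case_probands: int,
    n_control_probands: int,
    min_case_dnvs: int = 2,
    alpha: float = 0.05,
) -> ScreenResult:
    """De novo burden screen across genes/regions with Bonferroni correction.

    ``counts`` maps each unit to (case de novo carriers, control de novo
    carriers), or is a DataFrame with columns unit/case_carriers/
    control_carriers. Units with at least ``min_case_dnvs`` case variants
    are tested with :func:`fisher_exact` on the carriers-vs-rest table; the
    significance threshold is ``alpha / n_tests``.
    """
    if isinstance(counts, pd.DataFrame):
        items = [
            (str(r.unit), int(r.case_carriers), int(r.control_carriers))
            for r in counts.itertuples(index=False)
        ]
    else:
        items = [(str(u), int(c[0]), int(c[1])) for u, c in counts.items()]
    included = [(u, case, ctrl) for u, case, ctrl in items if case >= min_case_dnvs]
    n_tests = len(included)
    alpha_bonf = alpha / n_tests if n_tests else math.nan
    rows = []
    for unit, case, ctrl in included:
        table = ContingencyTable.from_carriers(case, n_case_probands, ctrl, n_control_probands)
        res = fisher_exact(table)
        rows.append(
            {
                "unit": unit,
                "case_carriers": case,
                "control_carriers": ctrl,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "significant": res.p_value < alpha_bonf,
            }
        )
    columns = [
        "unit", "case_carriers", "control_carriers",
        "odds_ratio", "ci_low", "ci_high", "p_value", "significant",
    ]
    return ScreenResult(pd.DataFrame(rows, columns=columns), n_tests, alpha, alpha_bonf)


def recurrent_dnv_screen(
    case_counts: Mapping[tuple, int],
    other_cohort_counts: Mapping[str, Mapping[tuple, int]],
    population_af: Mapping[tuple, float],
    min_ac: int = 3,
    max_pop_af: float = 0.005,
) -> pd.DataFrame:
    """Screen for recurrent case-exclusive de novo variants.

    A variant is retained when its case allele count is at least ``min_ac``,
    it is absent from every other cohort, and its population allele
    frequency does not exceed ``max_pop_af``. Returns one row per candidate
    (case AC >= min_ac) with the filter outcome, so near-misses are
    auditable.
    """
    rows = []
    for key, ac in sorted(case_counts.items()):
        if ac < min_ac:
            continue
        other = {name: int(tbl.get(key, 0)) for name, tbl in other_cohort_counts.items()}
        af = float(population_af.get(key, 0.0))
        absent_elsewhere = all(v == 0 for v in other.values())
        rare = af <= max_pop_af
        rows.append(
            {
                "variant": ":".join(str(k) for k in key),
                "case_ac": int(ac),
                **{f"ac_{name}": v for name, v in other.items()},
                "population_af": af,
                "absent_other_cohorts": absent_elsewhere,
                "below_max_pop_af": rare,
                "retained": absent_elsewhere and rare,
            }
        )
    return pd.DataFrame(rows)
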