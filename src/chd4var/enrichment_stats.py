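"""Exact 2x2 association statistics, implemented from first principles.

For a 2x2 table with fixed margins the cell count follows a hypergeometric
distribution; the two-sided Fisher exact p-value is the sum of the
probabilities of all margin-compatible tables whose probability does not
exceed that of the observed table (the sum-of-small-p convention used by
mainstream implementations; a double-one-sided variant is available).  The
association strength is reported as the sample (cross-product) odds ratio
``OR = a*d / (b*c)`` with the Katz log-normal confidence interval

    exp( ln OR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ).

In the CHD4 study the table of interest crosses variant location
(ATPase/helicase motor region vs. other domains) with reported heart
anomalies; :data:`STUDY_TABLE` packages the group counts behind the study's
printed statistics (19,1; 9,6 — fifteen informative other-domain variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .domain_architecture import DomainArchitecture
from .variant_model import ProteinVariant

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "STUDY_TABLE",
    "hypergeom_pmf",
    "fisher_exact_two_sided",
    "odds_ratio_katz_ci",
    "enrich",
]

#: Relative tolerance for probability ties in the two-sided sum, so the
#: observed table is never excluded by floating-point round-off.
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = group, columns = outcome (yes, no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


#: Group counts behind the study's printed enrichment statistics:
#: 19/1 heart anomalies among ATPase-motor-region variants vs 9/6 among the
#: informative other-domain variants (one variant uninformative/excluded).
STUDY_TABLE = ContingencyTable2x2(19, 1, 9, 6)

#: The table as the study's prose counts it ("nine of 16 in other domains").
#: It does NOT reproduce the printed p/OR/CI; kept so reports can surface both.
STUDY_TABLE_AS_WRITTEN = ContingencyTable2x2(19, 1, 9, 7)


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def feasible_range(margins: tuple[int, int, int, int]) -> tuple[int, int]:
    """Range [lo, hi] of the top-left cell compatible with the margins."""
    r1, r2, c1, c2 = margins
    return max(0, r1 - c2), min(r1, c1)


def hypergeom_pmf(a: int, margins: tuple[int, int, int, int]) -> float:
    """P(top-left cell = a) under fixed margins (r1, r2, c1, c2).

    Computed via log-gamma as C(c1, a) * C(c2, r1-a) / C(N, r1); sums to one
    over the feasible range.  Raises ``ValueError`` for an infeasible ``a``.
    """
    r1, r2, c1, c2 = margins
    if min(margins) < 0 or r1 + r2 != c1 + c2:
        raise ValueError(f"inconsistent margins {margins}")
    lo, hi = feasible_range(margins)
    if not (lo <= a <= hi):
        raise ValueError(f"cell {a} infeasible for margins {margins} (range {lo}..{hi})")
    n = r1 + r2
    return math.exp(_log_binom(c1, a) + _log_binom(c2, r1 - a) - _log_binom(n, r1))


def fisher_exact_two_sided(t: ContingencyTable2x2, *,
                           method: str = "sum_small_p") -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    ``method="sum_small_p"`` (default) sums the probabilities of all tables
    with the observed margins whose probability is at most the observed
    table's (with relative tie tolerance 1e-12); ``method="double_one_sided"``
    doubles the smaller tail probability, capped at 1.
    """
    margins = t.margins
    lo, hi = feasible_range(margins)
    pmf = [hypergeom_pmf(k, margins) for k in range(lo, hi + 1)]
    p_obs = pmf[t.a - lo]
    if method == "sum_small_p":
        p = sum(q for q in pmf if q <= p_obs * (1.0 + _TIE_RTOL))
    elif method == "double_one_sided":
        lower = sum(pmf[: t.a - lo + 1])
        upper = sum(pmf[t.a - lo:])
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(1.0, p)


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact-test p-value plus odds-ratio estimate with Katz CI."""

    table: ContingencyTable2x2
    p_two_sided: float
    odds_ratio: float          # may be inf/nan when a zero cell is present
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    excluded_unknowns: int = 0
    notes: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return math.isfinite(self.odds_ratio) and self.odds_ratio > 0.0

    def to_dict(self) -> dict:
        return {
            "table": list(self.table.cells),
            "p": self.p_two_sided,
            "or": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "excluded_unknowns": self.excluded_unknowns,
            "notes": list(self.notes),
        }


def _z_quantile(p: float) -> float:
    from scipy.special import ndtri  # standard-normal quantile only

    return float(ndtri(p))


def odds_ratio_katz_ci(t: ContingencyTable2x2, alpha: float = 0.05, *,
                       haldane: bool = False) -> EnrichmentResult:
    """Sample odds ratio with Katz log-normal (1 - alpha) confidence interval.

    With a zero cell the OR/CI are undefined (returned as nan) unless
    ``haldane=True`` adds the Haldane-Anscombe 0.5 continuity correction to
    every cell.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a, b, c, d = (x + 0.5 for x in t.cells) if haldane else tuple(float(x) for x in t.cells)
    notes: list[str] = []
    if haldane and 0 in t.cells:
        notes.append("Haldane-Anscombe 0.5 correction applied (zero cell)")
    if min(a, b, c, d) == 0.0:
        return EnrichmentResult(
            table=t, p_two_sided=fisher_exact_two_sided(t),
            odds_ratio=math.nan, ci_low=math.nan, ci_high=math.nan,
            alpha=alpha, notes=("odds ratio undefined: zero cell "
                                "(enable haldane correction to estimate)",))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = _z_quantile(1.0 - alpha / 2.0)
    log_or = math.log(or_)
    return EnrichmentResult(
        table=t,
        p_two_sided=fisher_exact_two_sided(t),
        odds_ratio=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        notes=tuple(notes),
    )


def enrich(variants: Sequence[ProteinVariant], region: str,
           arch: DomainArchitecture, alpha: float = 0.05, *,
           haldane: bool = False) -> EnrichmentResult:
    """Test heart-anomaly enrichment of variants inside ``region``.

    Builds the 2x2 table (region membership x heart anomaly) from the
    variants' protein spans and phenotype flags.  Variants with an unknown
    anomaly status or without a protein span are excluded and counted in
    ``excluded_unknowns``.  A zero margin makes the statistics undefined and
    is reported in ``notes``.
    """
    iv = arch[region]
    a = b = c = d = 0
    excluded = 0
    for v in variants:
        span = v.residue_span
        status = v.phenotype.heart_anomaly
        if span is None or status == "unknown":
            excluded += 1
            continue
        inside = iv.intersects(*span)
        if inside and status == "yes":
            a += 1
        elif inside:
            b += 1
        elif status == "yes":
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise ValueError("empty table: no informative variants")
    t = ContingencyTable2x2(a, b, c, d)
    if 0 in t.margins:
        return EnrichmentResult(
            table=t, p_two_sided=1.0, odds_ratio=math.nan,
            ci_low=math.nan, ci_high=math.nan, alpha=alpha,
            excluded_unknowns=excluded,
            notes=("statistics undefined: a table margin is zero",))
    res = odds_ratio_katz_ci(t, alpha, haldane=haldane)
    return EnrichmentResult(
        table=t, p_two_sided=res.p_two_sided, odds_ratio=res.odds_ratio,
        ci_low=res.ci_low, ci_high=res.ci_high, alpha=alpha,
        excluded_unknowns=excluded, notes=res.notes)
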