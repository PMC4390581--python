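"""2x2 association between motif presence and up-regulation.

The contingency table counts genes by (up-regulated?, has site?); the exact
test enumerates all tables with the observed margins in rational arithmetic
and sums hypergeometric probabilities no larger than the observed table's
(probability-ordering two-sided rule, with a 1e-7 relative guard for ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Callable, Mapping, Sequence

from .expression import RegulationCall

__all__ = [
    "ContingencyResult",
    "build_contingency",
    "fisher_exact_two_sided",
    "analyze_association",
    "contingency_report",
]

_TIE_GUARD = Fraction(10**7 + 1, 10**7)  # relative tolerance 1e-7 for ties


@dataclass(frozen=True)
class ContingencyResult:
    """Counts (a,b,c,d) = (up&site, up&no-site, not-up&site, not-up&no-site).

    ``odds_ratio`` is the sample odds ratio a*d/(b*c) (+inf when b*c = 0 and
    a*d > 0, NaN when undefined); ``p_two_sided`` is NaN until the exact
    test has been run.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = math.nan
    p_two_sided: float = math.nan
    method: str = "counts_only"
    flags: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(
    calls: Sequence[RegulationCall],
    has_site: Mapping[str, bool] | Callable[[str], bool],
    positive_label: str = "up",
) -> ContingencyResult:
    """Cross-tabulate regulation label against site presence (counts only)."""
    if callable(has_site):
        lookup = has_site
    else:
        missing = [c.gene_id for c in calls if c.gene_id not in has_site]
        if missing:
            raise KeyError(
                "genes missing from the site summary: " + ", ".join(sorted(missing))
            )
        lookup = has_site.__getitem__
    a = b = c_ = d = 0
    for call in calls:
        positive = call.label == positive_label
        site = bool(lookup(call.gene_id))
        if positive and site:
            a += 1
        elif positive:
            b += 1
        elif site:
            c_ += 1
        else:
            d += 1
    return ContingencyResult(a, b, c_, d)


def _hypergeom_pmf(k: int, total: int, successes: int, draws: int) -> Fraction:
    return Fraction(
        comb(successes, k) * comb(total - successes, draws - k), comb(total, draws)
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Exact two-sided Fisher test by hypergeometric enumeration.

    Returns ``(odds_ratio, p)``.  The p-value sums, over the feasible range
    of cell `a` at fixed margins, every table probability at most the
    observed one (relative tie tolerance 1e-7).  Any zero margin gives
    p = 1 and an undefined (NaN) odds ratio.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else math.nan
    else:
        odds_ratio = (a * d) / (b * c)
    total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        return odds_ratio, 1.0
    p_obs = _hypergeom_pmf(a, total, col1, row1)
    cutoff = p_obs * _TIE_GUARD
    lo = max(0, row1 - (total - col1))
    hi = min(col1, row1)
    p = Fraction(0)
    for k in range(lo, hi + 1):
        pk = _hypergeom_pmf(k, total, col1, row1)
        if pk <= cutoff:
            p += pk
    return odds_ratio, min(float(p), 1.0)


def analyze_association(
    calls: Sequence[RegulationCall],
    has_site: Mapping[str, bool] | Callable[[str], bool],
    positive_label: str = "up",
) -> ContingencyResult:
    """Build the table and attach the exact test result."""
    counts = build_contingency(calls, has_site, positive_label)
    odds_ratio, p = fisher_exact_two_sided(counts.a, counts.b, counts.c, counts.d)
    flags = ("undefined_odds_ratio",) if math.isnan(odds_ratio) else ()
    return ContingencyResult(
        counts.a,
        counts.b,
        counts.c,
        counts.d,
        odds_ratio=odds_ratio,
        p_two_sided=p,
        method="fisher_exact_two_sided_probability_ordering",
        flags=flags,
    )


def contingency_report(result: ContingencyResult) -> str:
    """Human-readable block for the pipeline report."""
    orr = (
        "undefined"
        if math.isnan(result.odds_ratio)
        else ("inf" if math.isinf(result.odds_ratio) else f"{result.odds_ratio:.4g}")
    )
    pr = "n/a" if math.isnan(result.p_two_sided) else f"{result.p_two_sided:.4g}"
    return (
        "motif presence vs up-regulation (n={n})\n"
        "                 site   no site\n"
        "  up             {a:>4}   {b:>7}\n"
        "  not up         {c:>4}   {d:>7}\n"
        "  odds ratio = {orr};  two-sided exact p = {p}\n"
    ).format(n=result.n, a=result.a, b=result.b, c=result.c, d=result.d, orr=orr, p=pr)
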