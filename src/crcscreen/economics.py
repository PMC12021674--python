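"""Discounting and cost-effectiveness arithmetic.

Additional cost, ICER, cost per life-year saved, prevented-case proportions,
the efficiency frontier with strict and extended dominance, and the
willingness-to-pay threshold conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CeaComparison",
    "FrontierEntry",
    "UndefinedIcerError",
    "discount_factor",
    "additional_cost",
    "icer",
    "cost_per_life_year_saved",
    "proportion_prevented",
    "efficiency_frontier",
    "wtp_threshold_usd",
    "is_highly_cost_effective",
    "cea_comparison",
]


class UndefinedIcerError(ValueError):
    """Raised when an ICER is requested for a zero effectiveness difference."""


@dataclass
class CeaComparison:
    """Pairwise comparison of a strategy against a reference."""

    reference: str
    comparator: str
    additional_cost: float
    life_years_saved: float
    icer: float | None
    dominated: bool = False
    extended_dominated: bool = False


@dataclass
class FrontierEntry:
    label: str
    total_cost: float
    life_years_saved: float
    dominated: bool = False
    extended_dominated: bool = False
    incremental_icer: float | None = None

    @property
    def on_frontier(self) -> bool:
        return not (self.dominated or self.extended_dominated)


def discount_factor(years_elapsed: float, rate: float) -> float:
    """(1 + rate) ** -years_elapsed."""
    if years_elapsed < 0:
        raise ValueError(f"years_elapsed must be >= 0, got {years_elapsed}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-years_elapsed)


def additional_cost(total_cost_comparator, total_cost_reference):
    """Comparator total cost minus reference total cost (exact for integers)."""
    return total_cost_comparator - total_cost_reference


def icer(delta_cost: float, delta_effect: float) -> float:
    """Additional cost per additional unit of effectiveness."""
    if delta_effect == 0:
        raise UndefinedIcerError(
            "ICER undefined for zero effectiveness difference"
        )
    return delta_cost / delta_effect


def cost_per_life_year_saved(total_cost: float, life_years_saved: float) -> float:
    if life_years_saved <= 0:
        raise ValueError(
            f"life_years_saved must be positive, got {life_years_saved}"
        )
    return total_cost / life_years_saved


def proportion_prevented(cases_reference: float, cases_strategy: float) -> float:
    """Percent of reference cases averted, rounded to one decimal place."""
    if cases_reference <= 0:
        raise ValueError("reference case count must be positive")
    return round(100.0 * (cases_reference - cases_strategy) / cases_reference, 1)


def cea_comparison(reference_label: str, reference_cost: float, reference_lyl: float,
                   comparator_label: str, comparator_cost: float, comparator_lyl: float) -> CeaComparison:
    """Build a pairwise comparison from total costs and life-years lost."""
    d_cost = additional_cost(comparator_cost, reference_cost)
    lys = reference_lyl - comparator_lyl
    try:
        ratio = icer(d_cost, lys)
    except UndefinedIcerError:
        ratio = None
    return CeaComparison(
        reference=reference_label,
        comparator=comparator_label,
        additional_cost=d_cost,
        life_years_saved=lys,
        icer=ratio,
    )


def efficiency_frontier(results: list[tuple[str, float, float]]) -> list[FrontierEntry]:
    """Order strategies by effectiveness and flag dominance.

    ``results`` holds (label, total_cost, life_years_saved) triples. Strictly
    dominated entries (another entry is at least as effective and at most as
    costly, strictly better in one — or an exact duplicate appearing earlier)
    are flagged first; extended dominance is then removed iteratively until
    incremental ICERs are strictly increasing along the frontier. Frontier
    members carry their incremental ICER versus the previous frontier member.
    """
    if len(results) < 2:
        raise ValueError("frontier needs at least two strategies")
    labels = [r[0] for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")

    entries = [
        FrontierEntry(label=lab, total_cost=float(c), life_years_saved=float(e))
        for lab, c, e in results
    ]

    for i, a in enumerate(entries):
        for j, b in enumerate(entries):
            if i == j:
                continue
            better = (
                b.life_years_saved >= a.life_years_saved and b.total_cost <= a.total_cost
            )
            strictly = (
                b.life_years_saved > a.life_years_saved or b.total_cost < a.total_cost
            )
            tie_first = (
                b.life_years_saved == a.life_years_saved
                and b.total_cost == a.total_cost
                and j < i
            )
            if better and (strictly or tie_first):
                a.dominated = True
                break

    active = sorted(
        [e for e in entries if not e.dominated],
        key=lambda e: (e.life_years_saved, e.total_cost),
    )

    # iterative extended-dominance removal
    changed = True
    while changed and len(active) > 2:
        changed = False
        for k in range(1, len(active) - 1):
            prev, cur, nxt = active[k - 1], active[k], active[k + 1]
            icer_in = _safe_icer(cur, prev)
            icer_out = _safe_icer(nxt, cur)
            if icer_in is not None and icer_out is not None and icer_in >= icer_out:
                cur.extended_dominated = True
                active.pop(k)
                changed = True
                break

    for k in range(1, len(active)):
        active[k].incremental_icer = _safe_icer(active[k], active[k - 1])

    return sorted(entries, key=lambda e: (e.life_years_saved, e.total_cost))


def _safe_icer(b: FrontierEntry, a: FrontierEntry) -> float | None:
    d_eff = b.life_years_saved - a.life_years_saved
    if d_eff == 0:
        return None
    return (b.total_cost - a.total_cost) / d_eff


def wtp_threshold_usd(gdp_per_capita_hkd: float, hkd_per_usd: float) -> int:
    """Convert a local-currency GDP-per-capita threshold to whole USD."""
    if gdp_per_capita_hkd <= 0 or hkd_per_usd <= 0:
        raise ValueError("inputs must be positive")
    return round(gdp_per_capita_hkd / hkd_per_usd)


def is_highly_cost_effective(icer_value: float, threshold_usd: float) -> bool:
    """A strategy is highly cost-effective when its ICER is below the threshold."""
    return icer_value < threshold_usd
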