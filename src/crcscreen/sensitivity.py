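"""One-way sensitivity analysis: parameter sweeps, tornado entries and the
compliance x kit-cost ICER grid.

Every swept point re-runs the full cohort model with all other parameters at
baseline; default ranges are +/-20% for probabilities (clipped to [0, 1]) and
+/-25% for costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics
from .engine import run_cohort
from .params import ParameterBundle, set_value
from .synthetic_epi import IncidenceTable, LifeTable

__all__ = [
    "SweepSpec",
    "TornadoEntry",
    "one_way_sweep",
    "tornado",
    "compliance_cost_grid",
    "default_tornado_specs",
    "icer_vs_reference",
    "threshold_crossing",
]


@dataclass(frozen=True)
class SweepSpec:
    parameter_key: str
    low: float
    high: float
    steps: int = 2

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"{self.parameter_key}: low must be < high")
        if self.steps < 2:
            raise ValueError(f"{self.parameter_key}: steps must be >= 2")

    def values(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.steps)


@dataclass(frozen=True)
class TornadoEntry:
    parameter_key: str
    icer_at_low: float
    icer_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def icer_vs_reference(
    strategy: str,
    reference: str,
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
) -> float:
    """ICER of *strategy* versus *reference* under the given parameters."""
    res_s = run_cohort(strategy, params, incidence, life)
    res_r = run_cohort(reference, params, incidence, life)
    comp = economics.cea_comparison(
        reference, res_r.total_cost, res_r.loss_of_life_years,
        strategy, res_s.total_cost, res_s.loss_of_life_years,
    )
    if comp.icer is None:
        raise economics.UndefinedIcerError(
            f"{strategy} vs {reference}: zero life-years saved"
        )
    return comp.icer


def one_way_sweep(
    spec: SweepSpec,
    strategy: str,
    reference: str,
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
) -> list[tuple[float, float]]:
    """Re-run the model at each swept value; returns (value, ICER) pairs."""
    out = []
    for v in spec.values():
        bundle = set_value(params, spec.parameter_key, float(v))
        out.append((float(v), icer_vs_reference(strategy, reference, bundle, incidence, life)))
    return out


def tornado(
    specs: list[SweepSpec],
    strategy: str,
    reference: str,
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
) -> list[TornadoEntry]:
    """One entry per parameter (ICER at range ends), widest bar first."""
    if not specs:
        raise ValueError("tornado needs at least one sweep spec")
    entries = []
    for spec in specs:
        lo = icer_vs_reference(
            strategy, reference, set_value(params, spec.parameter_key, spec.low),
            incidence, life,
        )
        hi = icer_vs_reference(
            strategy, reference, set_value(params, spec.parameter_key, spec.high),
            incidence, life,
        )
        entries.append(TornadoEntry(spec.parameter_key, lo, hi))
    return sorted(entries, key=lambda e: (-e.bar_width, e.parameter_key))


def compliance_cost_grid(
    costs: list[float],
    compliance_points: list[float],
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
    strategy: str = "colotect",
    reference: str = "none",
) -> pd.DataFrame:
    """ICER versus *reference* for each (kit cost, compliance) pair.

    Rows are compliance points, columns are kit costs.
    """
    if not costs or not compliance_points:
        raise ValueError("costs and compliance_points must be non-empty")
    for c in compliance_points:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"compliance {c} out of [0, 1]")
    grid = np.empty((len(compliance_points), len(costs)))
    for i, comp in enumerate(compliance_points):
        for j, cost in enumerate(costs):
            bundle = set_value(params, f"{strategy}.compliance", float(comp))
            bundle = set_value(bundle, f"{strategy}.cost", float(cost))
            grid[i, j] = icer_vs_reference(strategy, reference, bundle, incidence, life)
    return pd.DataFrame(grid, index=list(compliance_points), columns=list(costs))


def default_tornado_specs(params: ParameterBundle, strategy: str = "colotect") -> list[SweepSpec]:
    """Default ranges: +/-20% for probabilities (clipped), +/-25% for costs."""
    profile = getattr(params, strategy)
    specs = []

    def prob_spec(key: str, baseline: float) -> SweepSpec:
        return SweepSpec(key, max(0.0, baseline * 0.8), min(1.0, baseline * 1.2))

    specs.append(prob_spec(f"{strategy}.sensitivity", profile.sensitivity_crc))
    specs.append(prob_spec(f"{strategy}.specificity", profile.specificity_crc))
    specs.append(prob_spec(f"{strategy}.compliance", profile.compliance))
    specs.append(prob_spec(f"{strategy}.prevention", profile.prevention_fraction))
    specs.append(SweepSpec(f"{strategy}.cost", profile.unit_cost * 0.75, profile.unit_cost * 1.25))
    specs.append(prob_spec("colonoscopy.polypectomy_rate", params.colonoscopy.polypectomy_rate))
    specs.append(
        SweepSpec(
            "colonoscopy.cost",
            params.colonoscopy.unit_cost * 0.75,
            params.colonoscopy.unit_cost * 1.25,
        )
    )
    return specs


def threshold_crossing(
    parameter_key: str,
    lo: float,
    hi: float,
    wtp: float,
    strategy: str,
    reference: str,
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
    tol: float = 1e-4,
) -> float | None:
    """Bisect for the parameter value where the ICER crosses the WTP threshold.

    Returns None when the ICER sits on the same side of the threshold at both
    range ends.
    """
    def gap(v: float) -> float:
        bundle = set_value(params, parameter_key, float(v))
        return icer_vs_reference(strategy, reference, bundle, incidence, life) - wtp

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if g_lo * g_hi > 0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid == 0.0:
            return mid
        if g_lo * g_mid < 0:
            hi = mid
        else:
            lo, g_lo = mid, g_mid
    return 0.5 * (lo + hi)
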