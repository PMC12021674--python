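"""Result rendering: the per-strategy summary table, comparison rows and manifests.

Counts are rounded half-up to whole persons/procedures, currency to whole
USD, proportions to one decimal — matching the display precision of the
published layout the table mirrors.
"""

from __future__ import annotations

import json
import math
from datetime import datetime, timezone

import pandas as pd

from . import economics
from .engine import StrategyResult

__all__ = ["render_table3", "round_half_up", "write_manifest", "COLUMN_ORDER"]

COLUMN_ORDER = ("none", "fit", "colotect", "colonoscopy")

_COLUMN_TITLES = {
    "none": "No screening",
    "fit": "FIT",
    "colotect": "COLOTECT",
    "colonoscopy": "Colonoscopy",
}


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (for non-negative tallies)."""
    return int(math.floor(x + 0.5))


def _ledger(res: StrategyResult, key: str) -> float:
    return res.cost_ledger.get(key, 0.0)


def render_table3(results: dict[str, StrategyResult], reference: str = "none") -> pd.DataFrame:
    """Render per-strategy tallies in the canonical summary-table layout.

    Comparison rows (prevented cases, life-years saved, additional cost,
    ICERs) are filled only when the reference strategy is present; pairwise
    ICER rows appear for every screening strategy in canonical order.
    """
    if not results:
        raise ValueError("no results to render")
    order = [s for s in COLUMN_ORDER if s in results] + [
        s for s in results if s not in COLUMN_ORDER
    ]
    ref = results.get(reference)

    rows: dict[str, dict[str, object]] = {}

    def put(row: str, strat: str, value) -> None:
        rows.setdefault(row, {})[strat] = value

    for name in order:
        res = results[name]
        put("Total number CRC cases", name, round_half_up(res.crc_cases_total))
        put("Total loss of cancer-related life years", name,
            round_half_up(res.loss_of_life_years))
        if ref is not None:
            prevented = ref.crc_cases_total - res.crc_cases_total
            put("Cases of CRC prevented (compared with no screening)", name,
                round_half_up(prevented))
            put("Proportion of CRC case prevented (%)", name,
                economics.proportion_prevented(ref.crc_cases_total, res.crc_cases_total))
            put("Life-years saved", name,
                round_half_up(ref.loss_of_life_years - res.loss_of_life_years))

        put("Procedures: FIT", name,
            round_half_up(res.primary_tests if name == "fit" else 0.0))
        put("Procedures: COLOTECT", name,
            round_half_up(res.primary_tests if name == "colotect" else 0.0))
        put("Procedures: Colonoscopy", name, round_half_up(res.colonoscopies_total))
        put("Procedures: Diagnostic (without polypectomy)", name,
            round_half_up(res.colonoscopies_diagnostic))
        put("Procedures: Therapeutic (with polypectomy)", name,
            round_half_up(res.colonoscopies_therapeutic))

        put("Complications: Bleeding", name, round_half_up(res.bleeds))
        put("Complications: Perforations", name, round_half_up(res.perforations))

        put("Costs (USD): FIT", name, round_half_up(_ledger(res, "kits_fit")))
        put("Costs (USD): COLOTECT", name, round_half_up(_ledger(res, "kits_colotect")))
        put("Costs (USD): Colonoscopy", name,
            round_half_up(_ledger(res, "colonoscopy") + _ledger(res, "consultation")))
        put("Costs (USD): Polypectomy", name, round_half_up(_ledger(res, "polypectomy")))
        put("Costs (USD): Bleeding", name, round_half_up(_ledger(res, "bleeding")))
        put("Costs (USD): Perforations", name, round_half_up(_ledger(res, "perforation")))
        for i, stage in enumerate(("I", "II", "III", "IV"), start=1):
            put(f"Costs (USD): Care of CRC stage {stage}", name,
                round_half_up(_ledger(res, f"care_stage_{i}")))
        put("Costs (USD): Total", name, round_half_up(res.total_cost))

        if ref is not None and name != reference:
            lys = ref.loss_of_life_years - res.loss_of_life_years
            put("Total costs per life-years saved", name,
                round_half_up(economics.cost_per_life_year_saved(res.total_cost, lys))
                if lys > 0 else "")
            put("Additional cost", name,
                round_half_up(economics.additional_cost(res.total_cost, ref.total_cost)))

    # pairwise ICER rows in canonical order: each strategy versus every earlier one
    for bi, base in enumerate(order[:-1]):
        row_label = (
            "ICER versus no screening" if base == reference
            else f"ICER versus {_COLUMN_TITLES.get(base, base)}"
        )
        for name in order[bi + 1:]:
            res, res_base = results[name], results[base]
            lys = res_base.loss_of_life_years - res.loss_of_life_years
            if lys == 0:
                continue
            value = economics.icer(res.total_cost - res_base.total_cost, lys)
            put(row_label, name, round_half_up(value))

    # fill gaps before construction so integer cells stay integers
    full = {row: [vals.get(s, "") for s in order] for row, vals in rows.items()}
    df = pd.DataFrame.from_dict(full, orient="index", dtype=object)
    df.columns = [_COLUMN_TITLES.get(c, c) for c in order]
    df.index.name = "Outcome"
    return df


def write_manifest(path: str, **fields) -> None:
    """Write a JSON run manifest sufficient to reproduce the run."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **fields,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
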