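"""Comparator screening protocols expressed as schedules and eligibility rules.

Four strategies are supported:

* ``none`` — no screening ever.
* ``fit`` — annual stool FIT; positives referred to colonoscopy.
* ``colotect`` — annual multi-target stool-DNA test; positives referred.
* ``colonoscopy`` — primary colonoscopy, repeated 10 years after a normal
  result.

All screening strategies share a 3-year surveillance colonoscopy cycle after
polypectomy and a 10-year pause after a normal colonoscopy, after which the
person re-enters the primary screening pool (a pause expiring in the same
year a test is due resolves to performing the primary test that year).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StrategySchedule", "make_strategy", "due_for_screening", "STRATEGY_NAMES"]

STRATEGY_NAMES = ("none", "fit", "colotect", "colonoscopy")


@dataclass(frozen=True)
class StrategySchedule:
    name: str
    primary_modality: str  # none | stool_fit | stool_colotect | colonoscopy
    primary_interval: int | None
    surveillance_interval: int = 3
    post_normal_reset: int = 10
    referral_on_positive: bool = False

    @property
    def screens(self) -> bool:
        return self.primary_modality != "none"

    @property
    def is_stool(self) -> bool:
        return self.primary_modality in ("stool_fit", "stool_colotect")


def make_strategy(name: str) -> StrategySchedule:
    """Build the protocol schedule for a named strategy."""
    if name == "none":
        return StrategySchedule(name, "none", None)
    if name == "fit":
        return StrategySchedule(name, "stool_fit", 1, referral_on_positive=True)
    if name == "colotect":
        return StrategySchedule(name, "stool_colotect", 1, referral_on_positive=True)
    if name == "colonoscopy":
        return StrategySchedule(name, "colonoscopy", 10)
    raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}")


def due_for_screening(state, schedule: StrategySchedule, age: int, start_age: int = 50,
                      end_age: int = 75) -> tuple[float, float]:
    """Return (primary_due_mass, surveillance_due_mass) for the coming cycle.

    Primary-due mass is the well compartment plus any pause mass about to
    complete the 10-year reset (tie rule: it takes the primary test the year
    it re-enters). Surveillance-due mass is the portion of the surveillance
    clock completing the 3-year interval. Masses mid-pause or mid-surveillance
    are not due for anything.
    """
    if age < start_age or age > end_age:
        raise ValueError(f"age {age} outside model range [{start_age}, {end_age}]")
    if not schedule.screens:
        return 0.0, 0.0
    expiring_pause = float(state.pause[-1]) if len(state.pause) else 0.0
    primary = float(state.well) + expiring_pause
    surveillance = float(state.surveillance[-1]) if len(state.surveillance) else 0.0
    return primary, surveillance
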