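"""Deterministic Markov cohort engine and individual-level microsimulation oracle.

The cohort engine propagates expected fractional person-masses through annual
cycles from the starting age to the end of screening, then follows prevalent
cancer to extinction for life-year accounting. Within each cycle events occur
in a fixed order:

1. clock advancement (surveillance / post-normal pause / years-since-diagnosis),
2. the scheduled screening round (primary test, referral colonoscopies,
   surveillance colonoscopies, complications),
3. clinical diagnosis of cancers incident in the previous cycle that screening
   did not detect,
4. cancer incidence (reduced by the strategy's prevention fraction among the
   screen-protected mass),
5. stage-specific cancer mortality,
6. all-cause (other) mortality,

with costs and life-years accrued at the event time, discounted by
``(1 + r) ** -(age - start_age)``.

Undetected incident cancers spend exactly one cycle in an undiagnosed
compartment during which the next screening round may detect them (with the
test's sensitivity, yielding an earlier stage distribution); otherwise they
are diagnosed clinically with the baseline stage distribution.

``microsim_run`` replays the same event logic for ``n`` sampled individuals
with seeded randomness and scales tallies to cohort size; it serves as an
independent stochastic cross-check of the deterministic expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterBundle, ScreeningTestProfile, validate
from .strategies import StrategySchedule, make_strategy
from .synthetic_epi import IncidenceTable, LifeTable

__all__ = [
    "CohortState",
    "StrategyResult",
    "run_cohort",
    "microsim_run",
    "screening_round",
    "colonoscopy_round",
    "apply_incidence",
    "apply_stage_mortality",
    "apply_other_mortality",
    "life_years_lost",
    "shifted_stage_distribution",
    "expected_perforations",
]

STAGE_LABELS = ("I", "II", "III", "IV")


def shifted_stage_distribution(distribution, shift_fraction: float) -> np.ndarray:
    """Move a fraction of late-stage (III/IV) probability onto stages I/II.

    The removed late-stage mass is redistributed proportionally to the
    baseline early-stage weights; the result still sums to one.
    """
    d = np.asarray(distribution, dtype=float)
    moved = shift_fraction * d[2:].sum()
    early = d[:2] / d[:2].sum()
    out = d.copy()
    out[2:] *= 1.0 - shift_fraction
    out[:2] += moved * early
    return out


def expected_perforations(colonoscopies: float, perforation_rate: float) -> float:
    """Expected perforation events for a given colonoscopy volume."""
    return colonoscopies * perforation_rate


@dataclass
class CohortState:
    """Distribution of cohort mass over compartments at one cycle.

    ``surveillance[k]`` holds mass k completed years after a polypectomy;
    ``pause[j]`` holds mass j completed years after a normal colonoscopy;
    ``stage[i, s]`` holds mass diagnosed in stage i (I..III) s completed
    years ago; ``advanced`` pools stage IV plus relapsed stage III mass.
    """

    well: float
    opt_out: float = 0.0
    undiagnosed: float = 0.0
    undiagnosed_opt: float = 0.0
    surveillance: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pause: np.ndarray = field(default_factory=lambda: np.zeros(10))
    stage: np.ndarray = field(default_factory=lambda: np.zeros((3, 5)))
    advanced: float = 0.0
    cured: float = 0.0
    dead_crc: float = 0.0
    dead_other: float = 0.0
    dead_complication: float = 0.0

    @classmethod
    def initial(cls, cohort_size: float, settings) -> "CohortState":
        return cls(
            well=float(cohort_size),
            surveillance=np.zeros(settings.surveillance_interval),
            pause=np.zeros(settings.post_normal_reset),
            stage=np.zeros((3, settings.cure_years)),
        )

    def total(self) -> float:
        return (
            self.well
            + self.opt_out
            + self.undiagnosed
            + self.undiagnosed_opt
            + float(self.surveillance.sum())
            + float(self.pause.sum())
            + float(self.stage.sum())
            + self.advanced
            + self.cured
            + self.dead_crc
            + self.dead_other
            + self.dead_complication
        )


@dataclass
class StrategyResult:
    """Per-strategy tallies. Costs and life-years are discounted unless noted."""

    strategy: str
    start_age: int
    crc_cases_by_stage: np.ndarray = field(default_factory=lambda: np.zeros(4))
    crc_deaths_by_age: dict[int, float] = field(default_factory=dict)
    loss_of_life_years: float = 0.0
    loss_of_life_years_undiscounted: float = 0.0
    primary_tests: float = 0.0
    colonoscopies_total: float = 0.0
    colonoscopies_diagnostic: float = 0.0
    colonoscopies_therapeutic: float = 0.0
    bleeds: float = 0.0
    perforations: float = 0.0
    perforation_deaths: float = 0.0
    cost_ledger: dict[str, float] = field(default_factory=dict)
    cost_ledger_undiscounted: dict[str, float] = field(default_factory=dict)
    mass_audit: list[float] = field(default_factory=list)

    @property
    def crc_cases_total(self) -> float:
        return float(self.crc_cases_by_stage.sum())

    @property
    def crc_deaths_total(self) -> float:
        return float(sum(self.crc_deaths_by_age.values()))

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_ledger.values()))

    @property
    def total_cost_undiscounted(self) -> float:
        return float(sum(self.cost_ledger_undiscounted.values()))

    def add_cost(self, line: str, amount: float, disc: float) -> None:
        self.cost_ledger[line] = self.cost_ledger.get(line, 0.0) + amount * disc
        self.cost_ledger_undiscounted[line] = (
            self.cost_ledger_undiscounted.get(line, 0.0) + amount
        )


# ---------------------------------------------------------------------------
# Cycle-step operations (shared by run_cohort; individually unit-testable)
# ---------------------------------------------------------------------------

def advance_clocks(state: CohortState, settings) -> float:
    """Shift all clocks by one year; return surveillance mass now due.

    Pause mass completing the reset returns to the well compartment (and is
    screened in the same cycle, per the tie rule). Stage I/II mass completing
    the cure horizon moves to cured; stage III splits between cured and the
    advanced pool.
    """
    surv_due = float(state.surveillance[-1])
    state.surveillance[1:] = state.surveillance[:-1]
    state.surveillance[0] = 0.0

    released = float(state.pause[-1])
    state.pause[1:] = state.pause[:-1]
    state.pause[0] = 0.0
    state.well += released

    out = state.stage[:, -1].copy()
    state.stage[:, 1:] = state.stage[:, :-1]
    state.stage[:, 0] = 0.0
    p_cure3 = settings.stage3_cure_prob
    state.cured += out[0] + out[1] + p_cure3 * out[2]
    state.advanced += (1.0 - p_cure3) * out[2]
    return surv_due


def _diagnose(state: CohortState, res: StrategyResult, cases_mass: float,
              inflow_mass: float, distribution: np.ndarray, stage_params, disc: float) -> None:
    """Record diagnosed cases, accrue care costs, and seed stage compartments."""
    if cases_mass <= 0.0:
        return
    split_cases = cases_mass * distribution
    split_inflow = inflow_mass * distribution
    res.crc_cases_by_stage += split_cases
    for i in range(4):
        res.add_cost(f"care_stage_{i + 1}", split_cases[i] * stage_params.care_costs[i].total, disc)
    state.stage[:, 0] += split_inflow[:3]
    state.advanced += split_inflow[3]


def screening_round(
    state: CohortState,
    test: ScreeningTestProfile,
    params: ParameterBundle,
    attend_fraction: float | None = None,
) -> tuple[float, float, float, float]:
    """Apply one stool-test round; returns (referred_cancer, referred_clean, tests_used, protected_well).

    Attending mass is the well plus undiagnosed compartments times the
    attendance fraction (the test compliance unless overridden). Positives are
    true positives among undiagnosed attendees (sensitivity) plus false
    positives among well attendees (1 - specificity); both are referred to
    colonoscopy with the post-positive compliance. Referred mass is removed
    from its source compartment here; destination states are assigned by
    :func:`colonoscopy_round`. Negatives simply repeat next round.
    """
    c = test.compliance if attend_fraction is None else attend_fraction
    caf = params.colonoscopy.compliance_after_positive
    attending_well = state.well * c
    attending_undiag = state.undiagnosed * c
    tests_used = attending_well + attending_undiag

    true_pos = attending_undiag * test.sensitivity_crc
    false_pos = attending_well * (1.0 - test.specificity_crc)
    referred_cancer = true_pos * caf
    referred_clean = false_pos * caf

    state.undiagnosed -= referred_cancer
    state.well -= referred_clean
    protected_well = attending_well - referred_clean
    return referred_cancer, referred_clean, tests_used, protected_well


def colonoscopy_round(
    state: CohortState,
    res: StrategyResult,
    params: ParameterBundle,
    clean_mass: float,
    cancer_mass: float,
    surveillance_mass: float,
    disc: float,
    kit_line: str | None = None,
) -> None:
    """Perform colonoscopies, assigning destinations and accruing tallies/costs.

    Clean and surveillance colonoscopies split into therapeutic
    (polypectomy -> surveillance clock 0) and normal (-> pause clock 0);
    cancer colonoscopies diagnose with the screen-detected (stage-shifted)
    distribution. Complications: perforations, perforation deaths (removed
    proportionally from every destination) and bleeds per the configured
    basis. The per-strategy therapeutic tally uses the polypectomy rate
    applied to the full colonoscopy volume.
    """
    profile = params.colonoscopy
    total = clean_mass + cancer_mass + surveillance_mass
    if total <= 0.0:
        return
    pm = profile.perforation_mortality
    alive = 1.0 - pm
    poly_rate = profile.polypectomy_rate

    non_cancer = clean_mass + surveillance_mass
    therapeutic_in = non_cancer * poly_rate
    normal_in = non_cancer - therapeutic_in
    state.surveillance[0] += therapeutic_in * alive
    state.pause[0] += normal_in * alive

    shift = shifted_stage_distribution(
        params.stages.stage_distribution, params.settings.stage_shift_fraction
    )
    _diagnose(state, res, cancer_mass, cancer_mass * alive, shift, params.stages, disc)

    state.dead_complication += total * pm

    res.colonoscopies_total += total
    res.colonoscopies_therapeutic += total * poly_rate
    res.colonoscopies_diagnostic += total * (1.0 - poly_rate)
    perfs = total * profile.perforation_rate
    res.perforations += perfs
    res.perforation_deaths += total * pm
    if profile.bleeding_basis == "per_polypectomy":
        bleeds = total * poly_rate * profile.bleeding_rate
    else:
        bleeds = total * profile.bleeding_rate
    res.bleeds += bleeds

    res.add_cost("colonoscopy", total * profile.unit_cost, disc)
    res.add_cost("consultation", total * profile.consultation_cost, disc)
    res.add_cost("polypectomy", total * poly_rate * profile.histopathology_cost, disc)
    res.add_cost("bleeding", bleeds * profile.bleeding_cost, disc)
    res.add_cost("perforation", perfs * profile.perforation_cost, disc)


def apply_incidence(
    state: CohortState,
    rate: float,
    prevention: float,
    protected_well: float = 0.0,
) -> float:
    """Move newly incident cancer mass into the undiagnosed compartments.

    The screen-protected mass (this cycle's attending well mass plus all
    surveillance and pause mass) faces ``rate * (1 - prevention)``; the
    remaining well mass and permanent non-participants face the full rate.
    Returns the total newly incident mass.
    """
    r_protected = rate * (1.0 - prevention)
    protected_well = min(protected_well, state.well)

    cases_prot = protected_well * r_protected
    cases_unprot = (state.well - protected_well) * rate
    cases_opt = state.opt_out * rate
    surv_cases = state.surveillance * r_protected
    pause_cases = state.pause * r_protected

    state.well -= cases_prot + cases_unprot
    state.opt_out -= cases_opt
    state.surveillance -= surv_cases
    state.pause -= pause_cases

    new_participant = cases_prot + cases_unprot + float(surv_cases.sum()) + float(pause_cases.sum())
    state.undiagnosed += new_participant
    state.undiagnosed_opt += cases_opt
    return new_participant + cases_opt


def apply_stage_mortality(state: CohortState, stage_params) -> float:
    """Apply one year of stage-specific cancer mortality; returns deaths."""
    m = np.asarray(stage_params.annual_mortality, dtype=float)
    stage_deaths = state.stage * m[:3, None]
    adv_deaths = state.advanced * m[3]
    state.stage -= stage_deaths
    state.advanced -= adv_deaths
    deaths = float(stage_deaths.sum()) + adv_deaths
    state.dead_crc += deaths
    return deaths


def apply_other_mortality(state: CohortState, q: float) -> float:
    """Apply one year of all-cause (non-cancer) mortality to living compartments."""
    deaths = 0.0
    for name in ("well", "opt_out", "undiagnosed", "undiagnosed_opt", "advanced", "cured"):
        mass = getattr(state, name)
        d = mass * q
        setattr(state, name, mass - d)
        deaths += d
    for arr in (state.surveillance, state.pause, state.stage):
        deaths += float(arr.sum()) * q
        arr *= 1.0 - q
    state.dead_other += deaths
    return deaths


def life_years_lost(crc_deaths_by_age: dict[int, float], life: LifeTable,
                    discount_rate: float, start_age: int) -> float:
    """Sum of deaths(a) * remaining_life_expectancy(a) / (1 + r) ** (a - start_age)."""
    total = 0.0
    for age, deaths in crc_deaths_by_age.items():
        e = life.life_expectancy[age - int(life.ages[0])]
        total += deaths * e * (1.0 + discount_rate) ** -(age - start_age)
    return total


def _attendance(compliance: float, model: str, round_index: int) -> float:
    if model == "geometric_attrition":
        return compliance ** (round_index + 1)
    return compliance  # independent_per_round; once_ever handled via opt_out


# ---------------------------------------------------------------------------
# Cohort run
# ---------------------------------------------------------------------------

def run_cohort(
    strategy: str | StrategySchedule,
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
) -> StrategyResult:
    """Run the deterministic expected-value cohort model for one strategy."""
    schedule = strategy if isinstance(strategy, StrategySchedule) else make_strategy(strategy)
    violations = validate(params)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    s = params.settings
    if not incidence.covers(s.start_age, s.end_age):
        raise ValueError("incidence table does not cover the model ages")
    if not life.covers(s.start_age, s.closing_age - 1):
        raise ValueError("life table does not cover the model ages")

    if schedule.primary_modality == "stool_fit":
        test = params.fit
    elif schedule.primary_modality == "stool_colotect":
        test = params.colotect
    elif schedule.primary_modality == "colonoscopy":
        test = params.colonoscopy_test
    else:
        test = None

    state = CohortState.initial(s.cohort_size, s)
    res = StrategyResult(strategy=schedule.name, start_age=s.start_age)
    r = s.discount_rate
    round_index = 0

    for age in range(s.start_age, s.closing_age):
        t = age - s.start_age
        disc = (1.0 + r) ** (-t)
        in_screening_phase = age <= s.end_age

        surv_due = advance_clocks(state, s) if t > 0 else 0.0
        protected_well = 0.0

        if in_screening_phase and test is not None:
            attend = _attendance(test.compliance, s.attendance_model, round_index)
            if s.attendance_model == "once_ever":
                if round_index == 0:
                    refusers = state.well * (1.0 - test.compliance)
                    state.well -= refusers
                    state.opt_out += refusers
                attend = 1.0
            round_index += 1

            if schedule.is_stool:
                referred_cancer, referred_clean, tests, protected_well = screening_round(
                    state, test, params, attend_fraction=attend
                )
                res.primary_tests += tests
                kit_line = "kits_fit" if schedule.primary_modality == "stool_fit" else "kits_colotect"
                res.add_cost(kit_line, tests * test.unit_cost, disc)
                colonoscopy_round(
                    state, res, params, referred_clean, referred_cancer, surv_due, disc
                )
            else:  # primary colonoscopy: the pause clock enforces the 10-year interval
                attending_well = state.well * attend
                attending_undiag = state.undiagnosed * attend
                state.well -= attending_well
                state.undiagnosed -= attending_undiag
                res.primary_tests += attending_well + attending_undiag
                colonoscopy_round(
                    state, res, params, attending_well, attending_undiag, surv_due, disc
                )
        else:
            # no screening (or screening over): expired surveillance mass rejoins well
            state.well += surv_due

        # clinical diagnosis of cancers screening did not catch (1-year dwell)
        clinical = state.undiagnosed + state.undiagnosed_opt
        if clinical > 0.0:
            baseline_dist = np.asarray(params.stages.stage_distribution, dtype=float)
            _diagnose(state, res, clinical, clinical, baseline_dist, params.stages, disc)
            state.undiagnosed = 0.0
            state.undiagnosed_opt = 0.0

        if in_screening_phase:
            rate = incidence.rate_at(age)
            prevention = test.prevention_fraction if test is not None else 0.0
            apply_incidence(state, rate, prevention, protected_well)

        deaths = apply_stage_mortality(state, params.stages)
        if deaths > 0.0:
            res.crc_deaths_by_age[age] = res.crc_deaths_by_age.get(age, 0.0) + deaths

        apply_other_mortality(state, life.q_at(age))

        res.mass_audit.append(state.total())

        if not in_screening_phase:
            remaining_crc = (
                state.undiagnosed + state.undiagnosed_opt + float(state.stage.sum()) + state.advanced
            )
            if remaining_crc < 1e-12:
                break

    res.loss_of_life_years = life_years_lost(res.crc_deaths_by_age, life, r, s.start_age)
    res.loss_of_life_years_undiscounted = life_years_lost(
        res.crc_deaths_by_age, life, 0.0, s.start_age
    )
    return res


# ---------------------------------------------------------------------------
# Individual-level microsimulation (validation oracle)
# ---------------------------------------------------------------------------

_WELL, _OPTOUT, _UNDIAG, _SURV, _PAUSE = 0, 1, 2, 3, 4
_ST1, _ST2, _ST3, _ADV, _CURED = 5, 6, 7, 8, 9
_DEAD_CRC, _DEAD_OTHER, _DEAD_COMPL = 10, 11, 12


def microsim_run(
    strategy: str | StrategySchedule,
    params: ParameterBundle,
    incidence: IncidenceTable,
    life: LifeTable,
    n: int,
    seed: int,
) -> StrategyResult:
    """Simulate ``n`` independent life histories and scale tallies to cohort size.

    Mirrors the cohort engine's event ordering with per-person Bernoulli and
    categorical draws; deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    schedule = strategy if isinstance(strategy, StrategySchedule) else make_strategy(strategy)
    s = params.settings
    rng = np.random.default_rng(seed)
    scale = s.cohort_size / n

    if schedule.primary_modality == "stool_fit":
        test = params.fit
    elif schedule.primary_modality == "stool_colotect":
        test = params.colotect
    elif schedule.primary_modality == "colonoscopy":
        test = params.colonoscopy_test
    else:
        test = None

    profile = params.colonoscopy
    baseline_dist = np.asarray(params.stages.stage_distribution, dtype=float)
    shift_dist = shifted_stage_distribution(baseline_dist, s.stage_shift_fraction)
    base_cum = np.cumsum(baseline_dist)
    shift_cum = np.cumsum(shift_dist)
    mortality = np.asarray(params.stages.annual_mortality, dtype=float)
    stage_totals = np.array([c.total for c in params.stages.care_costs])

    status = np.full(n, _WELL, dtype=np.int8)
    clock = np.zeros(n, dtype=np.int16)

    res = StrategyResult(strategy=schedule.name, start_age=s.start_age)
    round_index = 0

    def diagnose(idx: np.ndarray, cum: np.ndarray, disc: float) -> None:
        if idx.size == 0:
            return
        stage_ix = np.searchsorted(cum, rng.random(idx.size), side="right")
        for k in range(4):
            res.crc_cases_by_stage[k] += np.count_nonzero(stage_ix == k) * scale
            res.add_cost(
                f"care_stage_{k + 1}",
                float(np.count_nonzero(stage_ix == k)) * stage_totals[k] * scale,
                disc,
            )
        new_status = np.where(stage_ix == 3, _ADV, _ST1 + stage_ix).astype(np.int8)
        status[idx] = new_status
        clock[idx] = 0

    def do_colonoscopies(clean_idx: np.ndarray, cancer_idx: np.ndarray, disc: float) -> None:
        total = clean_idx.size + cancer_idx.size
        if total == 0:
            return
        res.colonoscopies_total += total * scale
        poly_all = rng.random(total) < profile.polypectomy_rate
        n_poly = int(poly_all.sum())
        res.colonoscopies_therapeutic += n_poly * scale
        res.colonoscopies_diagnostic += (total - n_poly) * scale
        perf = rng.random(total) < profile.perforation_rate
        res.perforations += int(perf.sum()) * scale
        if profile.bleeding_basis == "per_polypectomy":
            bleed = poly_all & (rng.random(total) < profile.bleeding_rate)
        else:
            bleed = rng.random(total) < profile.bleeding_rate
        res.bleeds += int(bleed.sum()) * scale
        res.add_cost("colonoscopy", total * profile.unit_cost * scale, disc)
        res.add_cost("consultation", total * profile.consultation_cost * scale, disc)
        res.add_cost("polypectomy", n_poly * profile.histopathology_cost * scale, disc)
        res.add_cost("bleeding", int(bleed.sum()) * profile.bleeding_cost * scale, disc)
        res.add_cost("perforation", int(perf.sum()) * profile.perforation_cost * scale, disc)

        # destination assignment: clean colonoscopies use the polypectomy draw
        poly_clean = poly_all[: clean_idx.size]
        status[clean_idx[poly_clean]] = _SURV
        status[clean_idx[~poly_clean]] = _PAUSE
        clock[clean_idx] = 0
        diagnose(cancer_idx, shift_cum, disc)

        # perforation mortality overrides the destination
        death = rng.random(total) < profile.perforation_mortality
        all_idx = np.concatenate([clean_idx, cancer_idx])
        died = all_idx[death]
        status[died] = _DEAD_COMPL
        res.perforation_deaths += died.size * scale

    for age in range(s.start_age, s.closing_age):
        t = age - s.start_age
        disc = (1.0 + s.discount_rate) ** (-t)
        in_screening_phase = age <= s.end_age

        # 1. clocks
        surv_due = np.array([], dtype=np.intp)
        if t > 0:
            m = status == _SURV
            clock[m] += 1
            surv_due = np.flatnonzero(m & (clock == s.surveillance_interval))
            m = status == _PAUSE
            clock[m] += 1
            released = m & (clock == s.post_normal_reset)
            status[released] = _WELL
            for st in (_ST1, _ST2, _ST3):
                m = status == st
                clock[m] += 1
                done = np.flatnonzero(m & (clock == s.cure_years))
                if done.size:
                    if st == _ST3:
                        cure = rng.random(done.size) < s.stage3_cure_prob
                        status[done[cure]] = _CURED
                        status[done[~cure]] = _ADV
                    else:
                        status[done] = _CURED

        attended = np.zeros(n, dtype=bool)

        # 2. screening
        if in_screening_phase and test is not None:
            attend_p = _attendance(test.compliance, s.attendance_model, round_index)
            if s.attendance_model == "once_ever":
                if round_index == 0:
                    refuse = (status == _WELL) & (rng.random(n) >= test.compliance)
                    status[refuse] = _OPTOUT
                attend_p = 1.0
            round_index += 1

            eligible = (status == _WELL) | (status == _UNDIAG)
            attended = eligible & (rng.random(n) < attend_p)
            att_well = np.flatnonzero(attended & (status == _WELL))
            att_undiag = np.flatnonzero(attended & (status == _UNDIAG))
            res.primary_tests += (att_well.size + att_undiag.size) * scale

            if schedule.is_stool:
                kit_line = "kits_fit" if schedule.primary_modality == "stool_fit" else "kits_colotect"
                res.add_cost(kit_line, (att_well.size + att_undiag.size) * test.unit_cost * scale, disc)
                pos_cancer = att_undiag[rng.random(att_undiag.size) < test.sensitivity_crc]
                pos_clean = att_well[rng.random(att_well.size) < 1.0 - test.specificity_crc]
                caf = profile.compliance_after_positive
                ref_cancer = pos_cancer[rng.random(pos_cancer.size) < caf]
                ref_clean = pos_clean[rng.random(pos_clean.size) < caf]
                do_colonoscopies(np.concatenate([ref_clean, surv_due]), ref_cancer, disc)
            else:
                do_colonoscopies(np.concatenate([att_well, surv_due]), att_undiag, disc)
        elif surv_due.size:
            status[surv_due] = _WELL

        # 3. clinical diagnosis of remaining undiagnosed
        undiag = np.flatnonzero(status == _UNDIAG)
        diagnose(undiag, base_cum, disc)

        # 4. incidence
        if in_screening_phase:
            rate = incidence.rate_at(age)
            prevention = test.prevention_fraction if test is not None else 0.0
            protected = attended | (status == _SURV) | (status == _PAUSE)
            at_risk = (status == _WELL) | (status == _OPTOUT) | (status == _SURV) | (status == _PAUSE)
            eff_rate = np.where(protected, rate * (1.0 - prevention), rate)
            incident = at_risk & (rng.random(n) < eff_rate)
            status[incident] = _UNDIAG
            clock[incident] = 0

        # 5. cancer mortality
        deaths = 0
        for st, m_rate in ((_ST1, mortality[0]), (_ST2, mortality[1]), (_ST3, mortality[2]), (_ADV, mortality[3])):
            mask = status == st
            die = mask & (rng.random(n) < m_rate)
            k = int(die.sum())
            if k:
                status[die] = _DEAD_CRC
                deaths += k
        if deaths:
            res.crc_deaths_by_age[age] = res.crc_deaths_by_age.get(age, 0.0) + deaths * scale

        # 6. other-cause mortality
        alive = status < _DEAD_CRC
        die = alive & (rng.random(n) < life.q_at(age))
        status[die] = _DEAD_OTHER

        if not in_screening_phase and not np.any(
            (status == _UNDIAG) | ((status >= _ST1) & (status <= _ADV))
        ):
            break

    res.loss_of_life_years = life_years_lost(res.crc_deaths_by_age, life, s.discount_rate, s.start_age)
    res.loss_of_life_years_undiscounted = life_years_lost(res.crc_deaths_by_age, life, 0.0, s.start_age)
    return res
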