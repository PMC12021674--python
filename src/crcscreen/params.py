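"""Model parameters: dataclasses, defaults, config loading and validation.

All currency values are in USD. Probabilities are plain fractions in [0, 1].
The default bundle encodes the baseline estimates for test performance,
compliance, complication rates, cancer staging/mortality and unit costs used
by the cohort engine; any field can be overridden through a YAML config file
using dotted keys such as ``colotect.compliance`` or
``colonoscopy.perforation_rate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Any

import yaml

__all__ = [
    "ScreeningTestProfile",
    "ColonoscopyProfile",
    "StageCost",
    "StageParameters",
    "ModelSettings",
    "ParameterBundle",
    "ConfigError",
    "default_parameters",
    "load_config",
    "save_config",
    "set_value",
    "validate",
]


class ConfigError(ValueError):
    """Raised for unknown config keys, schema violations and out-of-range values."""


@dataclass(frozen=True)
class ScreeningTestProfile:
    """Performance, uptake and cost of a primary screening test."""

    name: str
    sensitivity_crc: float
    specificity_crc: float
    compliance: float
    unit_cost: float
    prevention_fraction: float
    interval_years: int = 1


@dataclass(frozen=True)
class ColonoscopyProfile:
    """Colonoscopy procedure costs, complication rates and referral compliance.

    ``bleeding_basis`` selects whether ``bleeding_rate`` applies per colonoscopy
    performed or per polypectomy. ``perforation_rate`` and
    ``perforation_mortality`` are always per colonoscopy.
    """

    unit_cost: float = 1259.0
    consultation_cost: float = 96.0
    histopathology_cost: float = 142.0
    polypectomy_rate: float = 0.1405
    bleeding_rate: float = 0.002
    bleeding_basis: str = "per_colonoscopy"  # or "per_polypectomy" (rate 0.0098)
    perforation_rate: float = 0.0008
    perforation_mortality: float = 0.000029
    bleeding_cost: float = 3320.0
    perforation_cost: float = 10790.0
    compliance_primary: float = 0.989
    compliance_after_positive: float = 1.0


@dataclass(frozen=True)
class StageCost:
    """Care cost components for one cancer stage.

    ``total`` is the authoritative figure used for cost accrual; the
    components are retained for reference and do not need to sum to it.
    """

    diagnosis: float
    treatment: float
    follow_up: float
    total: float


@dataclass(frozen=True)
class StageParameters:
    """Stage distribution at diagnosis, annual stage mortality and care costs."""

    stage_distribution: tuple[float, float, float, float] = (0.112, 0.245, 0.315, 0.328)
    annual_mortality: tuple[float, float, float, float] = (0.010, 0.045, 0.087, 0.430)
    care_costs: tuple[StageCost, StageCost, StageCost, StageCost] = (
        StageCost(6091.0, 10377.0, 603.0, 17071.0),
        StageCost(6091.0, 13061.0, 603.0, 19755.0),
        StageCost(6091.0, 20189.0, 603.0, 26883.0),
        StageCost(38422.0, 13061.0, 603.0, 45115.0),
    )


@dataclass(frozen=True)
class ModelSettings:
    """Global run settings for the cohort engine."""

    cohort_size: float = 100_000.0
    start_age: int = 50
    end_age: int = 75
    closing_age: int = 110
    discount_rate: float = 0.03
    cycle_length: int = 1
    hkd_to_usd: float = 0.13
    surveillance_interval: int = 3
    post_normal_reset: int = 10
    attendance_model: str = "independent_per_round"  # once_ever | geometric_attrition
    stage_shift_fraction: float = 0.5
    cure_years: int = 5
    stage3_cure_prob: float = 0.70
    rng_seed: int = 0


@dataclass(frozen=True)
class ParameterBundle:
    """Complete, immutable parameter set consumed by the engine."""

    fit: ScreeningTestProfile
    colotect: ScreeningTestProfile
    colonoscopy_test: ScreeningTestProfile
    colonoscopy: ColonoscopyProfile
    stages: StageParameters
    settings: ModelSettings


def default_parameters() -> ParameterBundle:
    """Return the immutable default parameter bundle."""
    return ParameterBundle(
        fit=ScreeningTestProfile(
            name="fit",
            sensitivity_crc=0.730,
            specificity_crc=0.919,
            compliance=0.600,
            unit_cost=19.0,
            prevention_fraction=0.210,
            interval_years=1,
        ),
        colotect=ScreeningTestProfile(
            name="colotect",
            sensitivity_crc=0.880,
            specificity_crc=0.920,
            compliance=0.9698,
            unit_cost=60.0,
            prevention_fraction=0.250,
            interval_years=1,
        ),
        colonoscopy_test=ScreeningTestProfile(
            name="colonoscopy",
            sensitivity_crc=1.0,
            specificity_crc=1.0,
            compliance=0.989,
            unit_cost=1259.0,
            prevention_fraction=0.540,
            interval_years=10,
        ),
        colonoscopy=ColonoscopyProfile(),
        stages=StageParameters(),
        settings=ModelSettings(),
    )


# ---------------------------------------------------------------------------
# Config key schema
# ---------------------------------------------------------------------------

# section name -> bundle attribute
_SECTIONS = {
    "fit": "fit",
    "colotect": "colotect",
    "colonoscopy_test": "colonoscopy_test",
    "colonoscopy": "colonoscopy",
    "stages": "stages",
    "settings": "settings",
}

# short aliases accepted in config files, per section type
_FIELD_ALIASES = {
    "sensitivity": "sensitivity_crc",
    "specificity": "specificity_crc",
    "cost": "unit_cost",
    "prevention": "prevention_fraction",
    "interval": "interval_years",
    "distribution": "stage_distribution",
    "mortality": "annual_mortality",
}

_PROBABILITY_FIELDS = {
    "sensitivity_crc",
    "specificity_crc",
    "compliance",
    "prevention_fraction",
    "polypectomy_rate",
    "bleeding_rate",
    "perforation_rate",
    "perforation_mortality",
    "compliance_primary",
    "compliance_after_positive",
    "stage_shift_fraction",
    "stage3_cure_prob",
}

_NONNEGATIVE_FIELDS = {
    "unit_cost",
    "consultation_cost",
    "histopathology_cost",
    "bleeding_cost",
    "perforation_cost",
    "discount_rate",
    "hkd_to_usd",
}

_POSITIVE_INT_FIELDS = {
    "interval_years",
    "surveillance_interval",
    "post_normal_reset",
    "cure_years",
    "cycle_length",
}

_ENUM_FIELDS = {
    "bleeding_basis": ("per_colonoscopy", "per_polypectomy"),
    "attendance_model": ("independent_per_round", "once_ever", "geometric_attrition"),
}

# stage cost shortcuts: stages.cost_i .. stages.cost_iv override the stage total
_STAGE_COST_KEYS = {"cost_i": 0, "cost_ii": 1, "cost_iii": 2, "cost_iv": 3}


def _check_field_range(key: str, name: str, value: Any) -> None:
    if name in _PROBABILITY_FIELDS:
        if not (isinstance(value, (int, float)) and 0.0 <= value <= 1.0):
            raise ConfigError(f"{key}: probability must lie in [0, 1], got {value!r}")
    elif name in _NONNEGATIVE_FIELDS:
        if not (isinstance(value, (int, float)) and value >= 0):
            raise ConfigError(f"{key}: value must be >= 0, got {value!r}")
    elif name in _POSITIVE_INT_FIELDS:
        if not (isinstance(value, int) and value >= 1):
            raise ConfigError(f"{key}: expected an integer >= 1, got {value!r}")
    elif name in _ENUM_FIELDS:
        if value not in _ENUM_FIELDS[name]:
            raise ConfigError(
                f"{key}: expected one of {_ENUM_FIELDS[name]}, got {value!r}"
            )
    elif name == "cohort_size":
        if not (isinstance(value, (int, float)) and value > 0):
            raise ConfigError(f"{key}: cohort size must be positive, got {value!r}")


def set_value(bundle: ParameterBundle, key: str, value: Any) -> ParameterBundle:
    """Return a copy of *bundle* with the dotted-key field replaced.

    Raises :class:`ConfigError` naming the offending key on unknown keys or
    out-of-range values.
    """
    parts = key.split(".")
    if len(parts) != 2:
        raise ConfigError(f"{key}: expected '<section>.<field>'")
    section_name, raw_field = parts
    if section_name not in _SECTIONS:
        raise ConfigError(f"{key}: unknown section {section_name!r}")
    section = getattr(bundle, _SECTIONS[section_name])

    if section_name == "stages" and raw_field in _STAGE_COST_KEYS:
        idx = _STAGE_COST_KEYS[raw_field]
        if not (isinstance(value, (int, float)) and value >= 0):
            raise ConfigError(f"{key}: value must be >= 0, got {value!r}")
        costs = list(section.care_costs)
        costs[idx] = replace(costs[idx], total=float(value))
        return replace(bundle, stages=replace(section, care_costs=tuple(costs)))

    field_name = _FIELD_ALIASES.get(raw_field, raw_field)
    names = {f.name for f in dataclasses.fields(section)}
    if field_name not in names:
        raise ConfigError(f"{key}: unknown field {raw_field!r}")

    if field_name in ("stage_distribution", "annual_mortality"):
        try:
            value = tuple(float(v) for v in value)
        except TypeError:
            raise ConfigError(f"{key}: expected a list of four numbers") from None
        if len(value) != 4:
            raise ConfigError(f"{key}: expected exactly four values")
        if any(not 0.0 <= v <= 1.0 for v in value):
            raise ConfigError(f"{key}: probabilities must lie in [0, 1]")
    else:
        _check_field_range(key, field_name, value)
        current = getattr(section, field_name)
        if isinstance(current, float) and isinstance(value, int):
            value = float(value)

    return replace(bundle, **{_SECTIONS[section_name]: replace(section, **{field_name: value})})


def _flatten(mapping: dict, prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for k, v in mapping.items():
        dotted = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, dotted + "."))
        else:
            flat[dotted] = v
    return flat


def load_config(path: str) -> ParameterBundle:
    """Load a YAML config file and return defaults overridden by its keys.

    An empty file yields the defaults. Unknown keys and out-of-range values
    raise :class:`ConfigError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    bundle = default_parameters()
    if raw is None:
        return bundle
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level of config must be a mapping")
    for key, value in sorted(_flatten(raw).items()):
        bundle = set_value(bundle, key, value)
    violations = validate(bundle)
    if violations:
        raise ConfigError("; ".join(violations))
    return bundle


def to_dict(bundle: ParameterBundle) -> dict:
    """Serialise the bundle to a nested plain dict (YAML-compatible)."""
    out: dict[str, Any] = {}
    for section_key, attr in _SECTIONS.items():
        section = getattr(bundle, attr)
        d = dataclasses.asdict(section)
        if section_key == "stages":
            d["stage_distribution"] = list(d["stage_distribution"])
            d["annual_mortality"] = list(d["annual_mortality"])
        d.pop("name", None)
        out[section_key] = d
    return out


def save_config(bundle: ParameterBundle, path: str) -> None:
    """Write the full bundle to YAML so it round-trips through load_config."""
    d = to_dict(bundle)
    # care_costs are not part of the override schema except totals
    costs = d["stages"].pop("care_costs")
    for key, idx in _STAGE_COST_KEYS.items():
        d["stages"][key] = costs[idx]["total"]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def validate(bundle: ParameterBundle) -> list[str]:
    """Return a list of invariant violations (empty iff the bundle is valid)."""
    v: list[str] = []

    for profile in (bundle.fit, bundle.colotect, bundle.colonoscopy_test):
        for name in ("sensitivity_crc", "specificity_crc", "compliance", "prevention_fraction"):
            x = getattr(profile, name)
            if not 0.0 <= x <= 1.0:
                v.append(f"{profile.name}.{name} out of [0, 1]: {x}")
        if profile.unit_cost < 0:
            v.append(f"{profile.name}.unit_cost negative: {profile.unit_cost}")
        if profile.interval_years < 1:
            v.append(f"{profile.name}.interval_years must be >= 1")

    c = bundle.colonoscopy
    for name in (
        "polypectomy_rate",
        "bleeding_rate",
        "perforation_rate",
        "perforation_mortality",
        "compliance_primary",
        "compliance_after_positive",
    ):
        x = getattr(c, name)
        if not 0.0 <= x <= 1.0:
            v.append(f"colonoscopy.{name} out of [0, 1]: {x}")
    for name in ("unit_cost", "consultation_cost", "histopathology_cost", "bleeding_cost", "perforation_cost"):
        x = getattr(c, name)
        if x < 0:
            v.append(f"colonoscopy.{name} negative: {x}")
    if c.perforation_mortality > c.perforation_rate:
        v.append("colonoscopy.perforation_mortality exceeds perforation_rate")
    if c.bleeding_basis not in _ENUM_FIELDS["bleeding_basis"]:
        v.append(f"colonoscopy.bleeding_basis invalid: {c.bleeding_basis!r}")

    st = bundle.stages
    total = sum(st.stage_distribution)
    if abs(total - 1.0) > 1e-9:
        v.append(f"stages.stage_distribution sums to {total}, expected 1")
    for i, m in enumerate(st.annual_mortality):
        if not 0.0 <= m <= 1.0:
            v.append(f"stages.annual_mortality[{i}] out of [0, 1]: {m}")
    for i, sc in enumerate(st.care_costs):
        for name in ("diagnosis", "treatment", "follow_up", "total"):
            x = getattr(sc, name)
            if x < 0:
                v.append(f"stages.care_costs[{i}].{name} negative: {x}")

    s = bundle.settings
    if not s.start_age < s.end_age:
        v.append(f"settings.start_age {s.start_age} must precede end_age {s.end_age}")
    if s.end_age >= s.closing_age:
        v.append("settings.end_age must precede closing_age")
    if s.discount_rate < 0:
        v.append(f"settings.discount_rate negative: {s.discount_rate}")
    if s.cohort_size <= 0:
        v.append(f"settings.cohort_size must be positive: {s.cohort_size}")
    if s.attendance_model not in _ENUM_FIELDS["attendance_model"]:
        v.append(f"settings.attendance_model invalid: {s.attendance_model!r}")
    for name in ("surveillance_interval", "post_normal_reset", "cure_years"):
        if getattr(s, name) < 1:
            v.append(f"settings.{name} must be >= 1")
    if not 0.0 <= s.stage_shift_fraction <= 1.0:
        v.append("settings.stage_shift_fraction out of [0, 1]")
    if not 0.0 <= s.stage3_cure_prob <= 1.0:
        v.append("settings.stage3_cure_prob out of [0, 1]")

    return v
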