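"""Synthetic epidemiological inputs: age-specific cancer incidence and a life table.

The real registry incidence extract and the reference life table behind the
analysis are not publicly deposited, so this module generates structurally
similar stand-ins: an exponentially age-increasing incidence curve over the
screening ages and a Gompertz–Makeham all-cause life table from which
remaining life expectancy is derived. Both can also be read from / written to
plain two-column delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IncidenceTable",
    "LifeTable",
    "gen_incidence",
    "gen_life_table",
    "remaining_life_expectancy",
    "default_incidence",
    "default_life_table",
    "read_incidence",
    "write_incidence",
    "read_life_table",
    "write_life_table",
    "expand_quinquennial",
]

MAX_RATE = 0.05  # upper clip for annual incidence rates


@dataclass(frozen=True)
class IncidenceTable:
    """Annual cancer incidence rate per person-year on an integer age grid."""

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.ages.shape != self.rates.shape:
            raise ValueError("ages and rates must have identical shape")

    def rate_at(self, age: int) -> float:
        idx = np.searchsorted(self.ages, age)
        if idx >= len(self.ages) or self.ages[idx] != age:
            raise KeyError(f"age {age} not covered by incidence table")
        return float(self.rates[idx])

    def covers(self, start_age: int, end_age: int) -> bool:
        return set(range(start_age, end_age + 1)) <= set(self.ages.tolist())


@dataclass(frozen=True)
class LifeTable:
    """All-cause annual mortality q(age) plus derived remaining life expectancy.

    Ages run from ``ages[0]`` to the closing age (``ages[-1] + 1``), at which
    any survivor is assumed to die. ``life_expectancy[i]`` is the expected
    number of future whole years lived from ``ages[i]``.
    """

    ages: np.ndarray
    qx: np.ndarray
    life_expectancy: np.ndarray = field(init=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape:
            raise ValueError("ages and qx must have identical shape")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("mortality probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        object.__setattr__(self, "life_expectancy", _expectancies(qx))

    @property
    def closing_age(self) -> int:
        return int(self.ages[-1]) + 1

    def q_at(self, age: int) -> float:
        i = age - int(self.ages[0])
        if i < 0 or i >= len(self.ages):
            raise KeyError(f"age {age} not covered by life table")
        return float(self.qx[i])

    def covers(self, start_age: int, end_age: int) -> bool:
        return int(self.ages[0]) <= start_age and int(self.ages[-1]) >= end_age


def _expectancies(qx: np.ndarray) -> np.ndarray:
    """e(a) = sum over k >= 1 of the probability of surviving k further years."""
    n = len(qx)
    e = np.zeros(n)
    for i in range(n - 1, -1, -1):
        p_survive = 1.0 - qx[i]
        nxt = e[i + 1] if i + 1 < n else 0.0
        e[i] = p_survive * (1.0 + nxt)
    return e


def gen_incidence(
    base_rate_at_50: float,
    log_slope: float = 0.0,
    seed: int = 0,
    jitter_sd: float = 0.0,
    start_age: int = 50,
    end_age: int = 75,
) -> IncidenceTable:
    """Generate rate(a) = base * exp(log_slope * (a - start_age)) with optional jitter.

    ``jitter_sd`` applies seeded multiplicative log-normal noise; zero gives a
    deterministic curve. Rates are clipped to [0, 0.05].
    """
    if base_rate_at_50 <= 0:
        raise ValueError(f"base_rate_at_50 must be positive, got {base_rate_at_50}")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    ages = np.arange(start_age, end_age + 1)
    rates = base_rate_at_50 * np.exp(log_slope * (ages - start_age))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates * np.exp(rng.normal(0.0, jitter_sd, size=len(ages)))
    return IncidenceTable(ages=ages, rates=np.clip(rates, 0.0, MAX_RATE))


def gen_life_table(
    makeham_a: float,
    gompertz_b: float,
    gompertz_c: float,
    start_age: int = 50,
    closing_age: int = 110,
) -> LifeTable:
    """Gompertz–Makeham life table: q(a) = min(1, a + b * exp(c * (age - start)))."""
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ValueError("life-table parameters must be >= 0")
    ages = np.arange(start_age, closing_age)
    qx = np.minimum(1.0, makeham_a + gompertz_b * np.exp(gompertz_c * (ages - start_age)))
    return LifeTable(ages=ages, qx=qx)


def remaining_life_expectancy(table: LifeTable, age: int) -> float:
    """Expected undiscounted future years lived from *age* under *table*."""
    i = age - int(table.ages[0])
    if i < 0 or i >= len(table.ages):
        raise KeyError(f"age {age} outside life table range")
    return float(table.life_expectancy[i])


def default_incidence(seed: int = 0, jitter_sd: float = 0.0) -> IncidenceTable:
    """Default synthetic incidence curve: ~60/100k at 50 rising to ~240/100k at 75."""
    return gen_incidence(6.0e-4, 0.055, seed=seed, jitter_sd=jitter_sd)


def default_life_table() -> LifeTable:
    """Default synthetic life table with East-Asian-like adult mortality levels."""
    return gen_life_table(1.0e-4, 1.8e-3, 0.09)


# ---------------------------------------------------------------------------
# Plain-text IO (two columns with a one-line header)
# ---------------------------------------------------------------------------

def write_incidence(table: IncidenceTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("age,rate\n")
        for a, r in zip(table.ages, table.rates):
            fh.write(f"{int(a)},{float(r)!r}\n")


def read_incidence(path: str) -> IncidenceTable:
    """Read an incidence table; quinquennial grids are expanded to annual."""
    ages, rates = _read_two_columns(path)
    if len(ages) >= 2 and np.all(np.diff(ages) == 5):
        ages, rates = expand_quinquennial(ages, rates)
    return IncidenceTable(ages=np.asarray(ages), rates=np.asarray(rates))


def expand_quinquennial(ages, rates) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 5-year age grid to annual by constant-within-band assignment."""
    ages = np.asarray(ages, dtype=int)
    rates = np.asarray(rates, dtype=float)
    out_ages, out_rates = [], []
    for i, (a, r) in enumerate(zip(ages, rates)):
        width = 5 if i + 1 < len(ages) else 1
        for k in range(width):
            out_ages.append(a + k)
            out_rates.append(r)
    return np.asarray(out_ages), np.asarray(out_rates)


def write_life_table(table: LifeTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("age,annual_mortality\n")
        for a, q in zip(table.ages, table.qx):
            fh.write(f"{int(a)},{float(q)!r}\n")


def read_life_table(path: str) -> LifeTable:
    ages, qx = _read_two_columns(path)
    return LifeTable(ages=np.asarray(ages), qx=np.asarray(qx))


def _read_two_columns(path: str) -> tuple[list[int], list[float]]:
    ages: list[int] = []
    vals: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        delim = "," if "," in header else None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, v = line.split(delim)[:2] if delim else line.split()[:2]
            ages.append(int(a))
            vals.append(float(v))
    return ages, vals
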