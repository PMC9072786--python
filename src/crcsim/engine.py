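"""Discrete-time individual-level natural-history engine.

One simulated person ages in 1-year cycles from 40 until death or 80.
Each cycle applies, in order: (1) any screening due at the current age,
(2) at most one forward step along the adenoma-carcinoma sequence,
(3) the cancer-specific death draw for people within 5 years of a
diagnosis, (4) the non-cancer death draw, then the birthday.  People
alive more than 5 years after a cancer diagnosis are treated as cured
("survivor rule": no further cancer-specific hazard).

Two surfaces are provided:

* scalar operations (:func:`draw_initial_state`, :func:`natural_transition`,
  :func:`advance_cycle`) acting on one :class:`Individual` — the semantic
  reference used by the unit tests;
* :func:`run_cohort`, a vectorized cohort run whose random draws come from
  purpose-keyed counter streams ``(seed, purpose, cycle)``.  Because every
  stream is indexed by individual position rather than consumed
  sequentially, two runs that share a seed use *common random numbers*:
  scenario comparisons differ only where screening actually intervened,
  and results are independent of iteration order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    AGE_MAX,
    AGE_MIN,
    SEXES,
    HealthState,
    InitialPrevalence,
    ParameterBundle,
    TransitionTable,
)

__all__ = [
    "Individual",
    "CohortResult",
    "CompiledBundle",
    "draw_initial_state",
    "natural_transition",
    "advance_cycle",
    "run_cohort",
    "stream",
]

#: Survivor rule: cancer-specific death hazard applies only while
#: years-since-diagnosis is in 0..4 (five annual draws).
SURVIVOR_YEARS = 5

HALF_CYCLE = 0.5  # person-year credit in the cycle of death or diagnosis


class Stream(enum.IntEnum):
    """Purpose codes for the counter-based random streams."""

    SEX = 0
    INITIAL_STATE = 1
    TRANSITION = 2
    CRC_DEATH = 3
    OTHER_DEATH = 4
    SCREEN_PARTICIPATION = 5
    SCREEN_TEST = 6
    SCREEN_REFERRAL = 7
    SCREEN_COLONOSCOPY = 8
    EVER_ATTENDER = 9


def stream(seed: int, purpose: int, *counters: int) -> np.random.Generator:
    """Deterministic generator keyed by ``(seed, purpose, *counters)``.

    Draws of shape ``(n,)`` from such a stream are positionally aligned
    across runs, which is what makes common-random-number comparisons
    between screening strategies exact.
    """
    return np.random.default_rng([int(seed), int(purpose), *map(int, counters)])


# ---------------------------------------------------------------------------
# scalar reference operations
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """One simulated person's evolving state."""

    id: int
    sex: str
    age: int = AGE_MIN
    state: HealthState = HealthState.NO_LESION
    years_since_dx: Optional[int] = None
    next_colonoscopy_due_age: Optional[int] = None
    is_attender: Optional[bool] = None

    @property
    def alive(self) -> bool:
        return not self.state.is_dead


def draw_initial_state(
    sex: str, initial_prevalence: Mapping[str, InitialPrevalence], rng: np.random.Generator
) -> HealthState:
    """Draw one of the four permitted age-40 states for ``sex``."""
    fractions = initial_prevalence[sex].fractions()
    u = rng.random()
    edges = np.cumsum(fractions)
    for code, edge in enumerate(edges):
        if u < edge:
            return HealthState(code)
    return HealthState.PRECLINICAL_CRC


def natural_transition(
    state: HealthState,
    sex: str,
    age: float,
    transitions: TransitionTable,
    rng: np.random.Generator,
) -> HealthState:
    """At most one forward step along the adenoma-carcinoma sequence.

    Preclinical cancer that progresses becomes *symptom-detected* cancer;
    all other lesion states advance one severity level.
    """
    if not state.is_undiagnosed:
        raise ValueError(f"natural_transition applies to undiagnosed states, got {state!r}")
    i = transitions.band_index_of(age)
    p = float(transitions.probs[sex][i, int(state)])
    if rng.random() < p:
        if state == HealthState.PRECLINICAL_CRC:
            return HealthState.CRC_SYMPTOM_DETECTED
        return HealthState(int(state) + 1)
    return state


@dataclass
class CycleEvents:
    """What happened to one individual during one cycle."""

    screened: bool = False
    incident_screen: bool = False
    incident_symptom: bool = False
    died_crc: bool = False
    died_other: bool = False
    person_years: float = 0.0


def advance_cycle(
    individual: Individual,
    bundle: ParameterBundle,
    strategy,
    rng: np.random.Generator,
) -> CycleEvents:
    """Advance one individual by one annual cycle, mutating it in place.

    ``strategy`` may be ``None`` (no screening).  The cycle order is
    screening → natural transition → cancer death → other-cause death →
    birthday; a lesion found and removed by screening therefore cannot
    also progress within the same cycle.
    """
    from . import screening as _screening  # deferred: avoids an import cycle

    if not individual.alive:
        raise ValueError(f"individual {individual.id} is dead")
    if individual.age >= AGE_MAX:
        raise ValueError(f"individual {individual.id} is beyond the simulation horizon")

    ev = CycleEvents()
    was_undiagnosed = individual.state.is_undiagnosed

    if strategy is not None and individual.state.is_undiagnosed:
        for event in _screening.due_events(strategy, individual):
            outcome = _screening.apply_screening_round(individual, event, strategy, bundle, rng)
            ev.screened = ev.screened or outcome.attended
            if outcome.crc_detected:
                ev.incident_screen = True
                break  # diagnosed: no further screening this cycle

    if individual.state.is_undiagnosed:
        new_state = natural_transition(
            individual.state, individual.sex, individual.age, bundle.transitions, rng
        )
        if new_state == HealthState.CRC_SYMPTOM_DETECTED:
            ev.incident_symptom = True
            individual.years_since_dx = 0
        individual.state = new_state

    if individual.state.is_diagnosed_crc and individual.years_since_dx < SURVIVOR_YEARS:
        q = bundle.crc_survival.adjusted_q(
            screen_detected=individual.state == HealthState.CRC_SCREEN_DETECTED
        )[individual.years_since_dx]
        if rng.random() < q:
            individual.state = HealthState.DEATH_CRC
            ev.died_crc = True

    if individual.alive:
        age_idx = individual.age - AGE_MIN
        p_other = float(bundle.life_table.non_crc_death(individual.sex)[age_idx])
        if rng.random() < p_other:
            individual.state = HealthState.DEATH_OTHER
            ev.died_other = True

    ev.person_years = HALF_CYCLE if (ev.died_crc or ev.died_other) else 1.0
    if individual.alive and individual.years_since_dx is not None:
        individual.years_since_dx += 1
    individual.age += 1
    return ev


# ---------------------------------------------------------------------------
# vectorized cohort engine
# ---------------------------------------------------------------------------


class CompiledBundle:
    """Dense-array view of a :class:`ParameterBundle` used by the
    vectorized engine: transition probabilities expanded to single ages,
    non-cancer death probabilities precomputed, survival profiles adjusted
    per detection mode."""

    def __init__(self, bundle: ParameterBundle):
        self.bundle = bundle
        n_ages = AGE_MAX - AGE_MIN  # cycles, ages 40..79
        self.trans = np.stack([bundle.transitions.by_age(sex) for sex in SEXES])  # (2,40,4)
        self.p_other = np.stack(
            [bundle.life_table.non_crc_death(sex) for sex in SEXES]
        )  # (2,41)
        self.q_symptom = bundle.crc_survival.adjusted_q(screen_detected=False)
        self.q_screen = bundle.crc_survival.adjusted_q(screen_detected=True)
        self.initial = np.stack(
            [bundle.initial_prevalence[sex].fractions() for sex in SEXES]
        )  # (2,4)
        self.sex_ratio = bundle.sex_ratio_at_entry

    def q_for(self, state: np.ndarray, ysd: np.ndarray) -> np.ndarray:
        """Annual cancer-death probability for diagnosed individuals."""
        idx = np.clip(ysd, 0, SURVIVOR_YEARS - 1)
        q = np.where(
            state == HealthState.CRC_SCREEN_DETECTED,
            self.q_screen[idx],
            self.q_symptom[idx],
        )
        return np.where(ysd < SURVIVOR_YEARS, q, 0.0)


@dataclass
class CohortResult:
    """Per-age event counts, occupancy and person-years for one simulated
    arm, split by sex (index 0 = male, 1 = female).

    Cycle arrays (length 40) are indexed by age at cycle start (40..79);
    occupancy arrays (length 41) are recorded at cycle start for ages
    40..80.  ``state_counts[a, s, k]`` counts individuals of sex ``s`` in
    state ``k`` at the start of age ``a``.
    """

    n: int
    seed: int
    strategy_name: str
    alive_start: np.ndarray  # (41, 2)
    state_counts: np.ndarray  # (41, 2, 8)
    inc_screen: np.ndarray  # (40, 2)
    inc_symptom: np.ndarray  # (40, 2)
    crc_deaths: np.ndarray  # (40, 2)
    other_deaths: np.ndarray  # (40, 2)
    py_mortality: np.ndarray  # (40, 2) exposure until death
    py_incidence: np.ndarray  # (40, 2) exposure until diagnosis or death

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, AGE_MAX + 1)

    @property
    def person_years(self) -> float:
        return float(self.py_mortality.sum())

    def incident_cases(self) -> np.ndarray:
        return self.inc_screen.sum(axis=1) + self.inc_symptom.sum(axis=1)

    def cumulative_incidence_per_100k(self) -> np.ndarray:
        """Cumulative diagnosed-cancer count per 100,000 cohort entrants at
        each age 40..80 (value at age a counts events in cycles < a, i.e.
        diagnoses made before the a-th birthday; the age-40 entry is the
        first cycle's count so that entry-year diagnoses are visible)."""
        c = np.concatenate([[0.0], np.cumsum(self.incident_cases())])
        c[0] = c[1]  # convention: show entry-cycle diagnoses at the entry age
        return 1e5 * c / self.n

    def cumulative_mortality_per_100k(self) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(self.crc_deaths.sum(axis=1))])
        c[0] = c[1]
        return 1e5 * c / self.n

    def _window_rate(self, events: np.ndarray, py: np.ndarray, grid: np.ndarray) -> np.ndarray:
        rates = np.zeros(len(grid))
        for i, a in enumerate(grid):
            lo = max(AGE_MIN, a - 5) if a > AGE_MIN else AGE_MIN
            hi = a if a > AGE_MIN else AGE_MIN + 1
            sl = slice(lo - AGE_MIN, hi - AGE_MIN)
            denom = py[sl].sum()
            rates[i] = 1e5 * events[sl].sum() / denom if denom > 0 else 0.0
        return rates

    def window_incidence_rate_per_100k(self, grid: Sequence[int] | None = None) -> np.ndarray:
        """Annualized diagnosis rate per 100,000 person-years in the 5-year
        window ending at each grid age (the age-40 entry uses the first
        cycle alone)."""
        grid = np.asarray(grid if grid is not None else np.arange(AGE_MIN, AGE_MAX + 1, 5))
        ev = self.inc_screen.sum(axis=1) + self.inc_symptom.sum(axis=1)
        return self._window_rate(ev, self.py_incidence.sum(axis=1), grid)

    def window_mortality_rate_per_100k(self, grid: Sequence[int] | None = None) -> np.ndarray:
        grid = np.asarray(grid if grid is not None else np.arange(AGE_MIN, AGE_MAX + 1, 5))
        return self._window_rate(
            self.crc_deaths.sum(axis=1), self.py_mortality.sum(axis=1), grid
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle age with pooled-sex counts and person-years."""
        a = np.arange(AGE_MIN, AGE_MAX)
        return pd.DataFrame(
            {
                "age": a,
                "alive_start": self.alive_start[:-1].sum(axis=1),
                "incident_screen": self.inc_screen.sum(axis=1),
                "incident_symptom": self.inc_symptom.sum(axis=1),
                "crc_deaths": self.crc_deaths.sum(axis=1),
                "other_deaths": self.other_deaths.sum(axis=1),
                "py_mortality": self.py_mortality.sum(axis=1),
                "py_incidence": self.py_incidence.sum(axis=1),
            }
        )


def run_cohort(
    n: int,
    bundle: ParameterBundle,
    strategy=None,
    horizon: int = AGE_MAX - AGE_MIN,
    seed: int = 0,
) -> CohortResult:
    """Simulate ``n`` independent individuals from age 40 for ``horizon``
    annual cycles (at most 40, i.e. to age 80).

    Identical ``(n, bundle, strategy, horizon, seed)`` give bit-identical
    results, and two strategies run under the same seed share every
    natural-history random draw (common random numbers).
    """
    from . import screening as _screening

    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not 1 <= horizon <= AGE_MAX - AGE_MIN:
        raise ValueError(f"horizon must be in 1..{AGE_MAX - AGE_MIN}")
    compiled = bundle if isinstance(bundle, CompiledBundle) else CompiledBundle(bundle.validate())

    sex_idx = (stream(seed, Stream.SEX).random(n) >= compiled.sex_ratio).astype(np.int8)
    u0 = stream(seed, Stream.INITIAL_STATE).random(n)
    cum = np.cumsum(compiled.initial, axis=1)  # (2,4)
    state = (u0[:, None] >= cum[sex_idx]).sum(axis=1).astype(np.int8)

    ysd = np.full(n, -1, dtype=np.int16)  # -1: never diagnosed
    next_colo_due = np.full(n, -1, dtype=np.int16)
    attender: dict[str, np.ndarray] = {}

    n_cycles = horizon
    alive_start = np.zeros((41, 2), dtype=np.int64)
    state_counts = np.zeros((41, 2, 8), dtype=np.int64)
    inc_screen = np.zeros((40, 2), dtype=np.int64)
    inc_symptom = np.zeros((40, 2), dtype=np.int64)
    crc_deaths = np.zeros((40, 2), dtype=np.int64)
    other_deaths = np.zeros((40, 2), dtype=np.int64)
    py_mort = np.zeros((40, 2))
    py_inc = np.zeros((40, 2))

    def tally(dest: np.ndarray, t: int, mask: np.ndarray) -> None:
        for s in (0, 1):
            dest[t, s] += int(np.count_nonzero(mask & (sex_idx == s)))

    def record_occupancy(t: int) -> None:
        for s in (0, 1):
            counts = np.bincount(state[sex_idx == s], minlength=8)
            state_counts[t, s] = counts
            alive_start[t, s] = counts[: HealthState.DEATH_CRC].sum()

    for t in range(n_cycles):
        age = AGE_MIN + t
        record_occupancy(t)
        alive = state < HealthState.DEATH_CRC
        undiag_at_start = state <= HealthState.PRECLINICAL_CRC

        # (1) screening
        if strategy is not None:
            events = [ev for ev in strategy.events if ev[0] == age]
            for k, (_, test_name) in enumerate(events):
                newly_screen_dx = _screening.screen_cohort_event(
                    state=state,
                    sex_idx=sex_idx,
                    ysd=ysd,
                    next_colo_due=next_colo_due,
                    attender=attender,
                    age=age,
                    test_name=test_name,
                    strategy=strategy,
                    compiled=compiled,
                    seed=seed,
                    cycle=t,
                    event_index=k,
                )
                tally(inc_screen, t, newly_screen_dx)

        # (2) natural progression (one forward step at most)
        undiag = (state <= HealthState.PRECLINICAL_CRC) & alive
        u = stream(seed, Stream.TRANSITION, t).random(n)
        p_fire = np.zeros(n)
        idx = np.flatnonzero(undiag)
        p_fire[idx] = compiled.trans[sex_idx[idx], t, state[idx]]
        fire = undiag & (u < p_fire)
        to_clinical = fire & (state == HealthState.PRECLINICAL_CRC)
        state[fire & ~to_clinical] += 1
        state[to_clinical] = HealthState.CRC_SYMPTOM_DETECTED
        ysd[to_clinical] = 0
        tally(inc_symptom, t, to_clinical)

        # (3) cancer-specific death within 5 years of diagnosis
        diagnosed = (state == HealthState.CRC_SCREEN_DETECTED) | (
            state == HealthState.CRC_SYMPTOM_DETECTED
        )
        u = stream(seed, Stream.CRC_DEATH, t).random(n)
        q = np.zeros(n)
        didx = np.flatnonzero(diagnosed)
        if didx.size:
            q[didx] = compiled.q_for(state[didx], ysd[didx])
        die_crc = diagnosed & (u < q)
        state[die_crc] = HealthState.DEATH_CRC
        tally(crc_deaths, t, die_crc)

        # (4) non-cancer death
        alive = state < HealthState.DEATH_CRC
        u = stream(seed, Stream.OTHER_DEATH, t).random(n)
        die_other = alive & (u < compiled.p_other[sex_idx, t])
        state[die_other] = HealthState.DEATH_OTHER
        tally(other_deaths, t, die_other)

        # person-years: full credit if the cycle was survived, half otherwise
        alive_end = state < HealthState.DEATH_CRC
        died = die_crc | die_other
        undiag_end = state <= HealthState.PRECLINICAL_CRC
        exited_incidence = undiag_at_start & (~undiag_end | died)
        for s in (0, 1):
            m = sex_idx == s
            py_mort[t, s] = np.count_nonzero(alive_end & m) + HALF_CYCLE * np.count_nonzero(
                died & m
            )
            py_inc[t, s] = np.count_nonzero(
                undiag_end & alive_end & m
            ) + HALF_CYCLE * np.count_nonzero(exited_incidence & m)

        ysd[alive_end & (ysd >= 0)] += 1

    record_occupancy(n_cycles)
    if n_cycles < 40:  # pad occupancy beyond the horizon with the final snapshot
        for t in range(n_cycles + 1, 41):
            state_counts[t] = state_counts[n_cycles]
            alive_start[t] = alive_start[n_cycles]

    return CohortResult(
        n=n,
        seed=seed,
        strategy_name=getattr(strategy, "name", "no_screening"),
        alive_start=alive_start,
        state_counts=state_counts,
        inc_screen=inc_screen,
        inc_symptom=inc_symptom,
        crc_deaths=crc_deaths,
        other_deaths=other_deaths,
        py_mortality=py_mort,
        py_incidence=py_inc,
    )
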