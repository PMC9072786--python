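"""Two-arm sigmoidoscopy screening-trial emulation.

Emulates a per-protocol comparison in the style of the large UK one-off
flexible-sigmoidoscopy trial: a usual-care control arm and a screened
arm that receives a single sigmoidoscopy at trial entry (attendance
100%, since per-protocol analysis conditions on attendance), with
advanced findings referred to colonoscopy.  Entry ages are drawn
uniformly over an age range; each participant is followed for a fixed
(possibly fractional) number of years, with the final partial year
handled by scaling that cycle's hazards on the hazard-power scale and
crediting the fractional exposure.

Participants are recruited from the simulated birth cohort: anyone dead
or already diagnosed at their entry age is ineligible and replaced from
an oversampled pool, so both arms start disease-undiagnosed and alive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .engine import AGE_MIN, AGE_MAX, CompiledBundle, HALF_CYCLE, Stream, stream
from .params import HealthState, ParameterBundle
from .screening import SIGMOIDOSCOPY, Strategy, screen_cohort_event

__all__ = [
    "TrialArmResult",
    "TrialResult",
    "run_two_arm_trial",
    "event_rate_per_100k",
    "rate_ratio_hr",
]


def event_rate_per_100k(cases: float, person_years: float) -> float:
    """Events per 100,000 person-years (unrounded; round for display)."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1e5 * cases / person_years


def rate_ratio_hr(screened_rate: float, control_rate: float) -> float:
    """Screened/control rate ratio, the trial's summary hazard ratio."""
    if control_rate <= 0:
        raise ValueError("control rate must be positive")
    return screened_rate / control_rate


@dataclass
class TrialArmResult:
    """Event counts, exposures and rates for one trial arm.

    Incidence and mortality keep separate person-year denominators:
    incidence exposure is censored at diagnosis, mortality exposure at
    death, both with half-cycle credit in the event cycle (one tenth of
    a cycle when the event falls in the fractional final period).
    """

    n: int
    cases: int
    crc_deaths: int
    other_deaths: int
    py_incidence: float
    py_mortality: float

    @property
    def all_deaths(self) -> int:
        return self.crc_deaths + self.other_deaths

    @property
    def incidence_rate(self) -> float:
        return event_rate_per_100k(self.cases, self.py_incidence)

    @property
    def crc_mortality_rate(self) -> float:
        return event_rate_per_100k(self.crc_deaths, self.py_mortality)

    @property
    def all_cause_mortality_rate(self) -> float:
        return event_rate_per_100k(self.all_deaths, self.py_mortality)

    @property
    def non_crc_mortality_rate(self) -> float:
        return event_rate_per_100k(self.other_deaths, self.py_mortality)


@dataclass
class TrialResult:
    control: TrialArmResult
    screened: TrialArmResult

    @property
    def hr_incidence(self) -> float:
        return rate_ratio_hr(self.screened.incidence_rate, self.control.incidence_rate)

    @property
    def hr_crc_mortality(self) -> float:
        return rate_ratio_hr(self.screened.crc_mortality_rate, self.control.crc_mortality_rate)

    @property
    def hr_all_cause(self) -> float:
        return rate_ratio_hr(
            self.screened.all_cause_mortality_rate, self.control.all_cause_mortality_rate
        )

    @property
    def hr_non_crc(self) -> float:
        return rate_ratio_hr(
            self.screened.non_crc_mortality_rate, self.control.non_crc_mortality_rate
        )

    def to_frame(self) -> pd.DataFrame:
        """Side-by-side table of counts, person-years, rates and HRs."""
        rows = []
        for metric, attr, py in (
            ("incidence", "cases", "py_incidence"),
            ("all_cause_mortality", "all_deaths", "py_mortality"),
            ("crc_mortality", "crc_deaths", "py_mortality"),
            ("non_crc_mortality", "other_deaths", "py_mortality"),
        ):
            hr = {
                "incidence": self.hr_incidence,
                "all_cause_mortality": self.hr_all_cause,
                "crc_mortality": self.hr_crc_mortality,
                "non_crc_mortality": self.hr_non_crc,
            }[metric]
            for arm_name, arm in (("control", self.control), ("screened", self.screened)):
                events = getattr(arm, attr)
                exposure = getattr(arm, py)
                rows.append(
                    {
                        "metric": metric,
                        "arm": arm_name,
                        "n": arm.n,
                        "events": events,
                        "person_years": exposure,
                        "rate_per_100k": event_rate_per_100k(events, exposure),
                        "hazard_ratio": hr,
                    }
                )
        return pd.DataFrame(rows)


class _PoolExhausted(RuntimeError):
    def __init__(self, eligible: int, pool: int):
        self.eligible, self.pool = eligible, pool
        super().__init__(f"only {eligible} eligible participants in a pool of {pool}")


def _simulate_arm(
    n_arm: int,
    compiled: CompiledBundle,
    entry_ages: tuple[int, int],
    followup_years: float,
    seed: int,
    screened: bool,
    strategy: Strategy,
    oversample: float = 1.5,
) -> TrialArmResult:
    """Simulate one arm: natural history from age 40, the entry-age
    eligibility filter, the optional entry sigmoidoscopy, and windowed
    event/exposure accounting."""
    n_pool = int(math.ceil(n_arm * oversample))
    full_cycles = int(math.floor(followup_years + 1e-9))
    frac = followup_years - full_cycles
    if frac < 1e-9:
        frac = 0.0

    sex_idx = (stream(seed, Stream.SEX).random(n_pool) >= compiled.sex_ratio).astype(np.int8)
    u0 = stream(seed, Stream.INITIAL_STATE).random(n_pool)
    cum = np.cumsum(compiled.initial, axis=1)
    state = (u0[:, None] >= cum[sex_idx]).sum(axis=1).astype(np.int8)
    ysd = np.full(n_pool, -1, dtype=np.int16)
    next_colo_due = np.full(n_pool, -1, dtype=np.int16)
    attender: dict = {}

    lo, hi = entry_ages
    entry = lo + (stream(seed, Stream.EVER_ATTENDER, 101).random(n_pool) * (hi - lo + 1)).astype(
        np.int64
    )
    entry = np.minimum(entry, hi)

    eligible = np.zeros(n_pool, dtype=bool)
    # per-individual follow-up clock in cycles since entry; -1 before entry
    case_cycle = np.full(n_pool, -1, dtype=np.int64)
    crc_death_cycle = np.full(n_pool, -1, dtype=np.int64)
    other_death_cycle = np.full(n_pool, -1, dtype=np.int64)
    case_is_screen = np.zeros(n_pool, dtype=bool)

    last_entry = hi
    horizon = last_entry - AGE_MIN + full_cycles + (1 if frac > 0 else 0)
    for t in range(horizon):
        age = AGE_MIN + t
        at_entry = entry == age
        if at_entry.any():
            eligible |= at_entry & (state <= HealthState.PRECLINICAL_CRC)
        rel = np.where(age >= entry, age - entry, -1)  # cycle index within follow-up
        in_full = (rel >= 0) & (rel < full_cycles)
        in_frac = (rel == full_cycles) & (frac > 0)
        in_window = in_full | in_frac

        # entry screening (per-protocol: every eligible screened participant attends)
        if screened and at_entry.any():
            mask_entry = at_entry & eligible
            if mask_entry.any():
                crc_found = screen_cohort_event(
                    state=state,
                    sex_idx=sex_idx,
                    ysd=ysd,
                    next_colo_due=next_colo_due,
                    attender=attender,
                    age=age,
                    test_name=SIGMOIDOSCOPY,
                    strategy=strategy,
                    compiled=compiled,
                    seed=seed,
                    cycle=t,
                    event_index=0,
                    offer_mask=mask_entry,
                )
                newly = crc_found & (case_cycle < 0)
                case_cycle[newly] = rel[newly]
                case_is_screen[newly] = True

        alive = state < HealthState.DEATH_CRC
        undiag = (state <= HealthState.PRECLINICAL_CRC) & alive
        frac_mask = in_frac  # hazards scaled in the fractional final cycle

        # natural progression
        if t < AGE_MAX - AGE_MIN:
            u = stream(seed, Stream.TRANSITION, t).random(n_pool)
            p_fire = np.zeros(n_pool)
            idx = np.flatnonzero(undiag)
            p_fire[idx] = compiled.trans[sex_idx[idx], t, state[idx]]
            p_fire = np.where(frac_mask, -np.expm1(frac * np.log1p(-p_fire)), p_fire)
            fire = undiag & (u < p_fire)
            to_clin = fire & (state == HealthState.PRECLINICAL_CRC)
            state[fire & ~to_clin] += 1
            state[to_clin] = HealthState.CRC_SYMPTOM_DETECTED
            ysd[to_clin] = 0
            newly = to_clin & (case_cycle < 0) & (rel >= 0) & in_window
            case_cycle[newly] = rel[newly]

        # cancer-specific death
        diagnosed = (state == HealthState.CRC_SCREEN_DETECTED) | (
            state == HealthState.CRC_SYMPTOM_DETECTED
        )
        u = stream(seed, Stream.CRC_DEATH, t).random(n_pool)
        q = np.zeros(n_pool)
        didx = np.flatnonzero(diagnosed)
        if didx.size:
            q[didx] = compiled.q_for(state[didx], ysd[didx])
        q = np.where(frac_mask, -np.expm1(frac * np.log1p(-q)), q)
        die_crc = diagnosed & (u < q)
        state[die_crc] = HealthState.DEATH_CRC
        newly = die_crc & in_window & (crc_death_cycle < 0)
        crc_death_cycle[newly] = rel[newly]

        # other-cause death
        alive = state < HealthState.DEATH_CRC
        u = stream(seed, Stream.OTHER_DEATH, t).random(n_pool)
        p_other = compiled.p_other[sex_idx, min(t, AGE_MAX - AGE_MIN)]
        p_other = np.where(frac_mask, -np.expm1(frac * np.log1p(-p_other)), p_other)
        die_other = alive & (u < p_other)
        state[die_other] = HealthState.DEATH_OTHER
        newly = die_other & in_window & (other_death_cycle < 0)
        other_death_cycle[newly] = rel[newly]

        ysd[(state < HealthState.DEATH_CRC) & (ysd >= 0)] += 1

    chosen = np.flatnonzero(eligible)
    if chosen.size < n_arm:
        raise _PoolExhausted(chosen.size, n_pool)
    chosen = chosen[:n_arm]

    def event_time(cycle_idx: np.ndarray) -> np.ndarray:
        """Time (years from entry) credited up to an event in the given
        follow-up cycle; half-cycle credit within the event's cycle."""
        t_ev = cycle_idx + HALF_CYCLE
        if frac > 0:
            t_ev = np.where(cycle_idx == full_cycles, full_cycles + HALF_CYCLE * frac, t_ev)
        return t_ev

    cc = case_cycle[chosen]
    dc = crc_death_cycle[chosen]
    oc = other_death_cycle[chosen]
    death_cycle = np.where(dc >= 0, dc, oc)
    death_cycle = np.where((dc >= 0) & (oc >= 0), np.minimum(dc, oc), death_cycle)

    t_death = np.where(death_cycle >= 0, event_time(death_cycle), followup_years)
    py_mort = float(np.sum(t_death))

    # incidence exposure: censored at diagnosis or death, whichever first
    first = np.where(cc >= 0, cc, np.iinfo(np.int64).max)
    first = np.minimum(first, np.where(death_cycle >= 0, death_cycle, np.iinfo(np.int64).max))
    t_inc = np.where(first < np.iinfo(np.int64).max, event_time(first), followup_years)
    py_inc = float(np.sum(t_inc))

    return TrialArmResult(
        n=int(n_arm),
        cases=int(np.count_nonzero(cc >= 0)),
        crc_deaths=int(np.count_nonzero(dc >= 0)),
        other_deaths=int(np.count_nonzero((oc >= 0) & ((dc < 0) | (oc < dc)))),
        py_incidence=py_inc,
        py_mortality=py_mort,
    )


def run_two_arm_trial(
    bundle: ParameterBundle,
    n_control: int = 112_939,
    n_screened: int = 40_621,
    entry_age_range: tuple[int, int] = (55, 64),
    followup_years: float = 11.2,
    seed: int = 0,
) -> TrialResult:
    """Emulate the two-arm one-off sigmoidoscopy trial per-protocol.

    Control arm: no screening.  Screened arm: one sigmoidoscopy at trial
    entry with 100% attendance; advanced adenomas and cancers found are
    referred to colonoscopy (completion per the strategy default, 0.96).
    Returns rates per 100,000 person-years and rate-ratio HRs for
    incidence, cancer mortality, all-cause and non-cancer mortality.
    """
    if n_control < 1 or n_screened < 1:
        raise ValueError("arm sizes must be >= 1")
    if followup_years <= 0:
        raise ValueError("follow-up must be positive")
    lo, hi = entry_age_range
    if not (AGE_MIN <= lo <= hi < AGE_MAX):
        raise ValueError(f"entry age range {entry_age_range} outside model coverage")
    compiled = CompiledBundle(bundle.validate())
    strategy = Strategy(
        name="one_off_sigmoidoscopy",
        events=(),  # the entry sigmoidoscopy is scheduled per-individual
        participation={SIGMOIDOSCOPY: 1.0},
    )
    def arm(n_arm: int, arm_seed: int, is_screened: bool) -> TrialArmResult:
        # recruitment pool grows until enough alive-and-undiagnosed
        # participants exist at entry; draws are positionally keyed, so a
        # larger pool extends rather than reshuffles the randomness
        oversample = 1.5
        while True:
            try:
                return _simulate_arm(
                    n_arm, compiled, (lo, hi), followup_years, arm_seed,
                    is_screened, strategy, oversample=oversample,
                )
            except _PoolExhausted:
                if oversample > 64:
                    raise
                oversample *= 2.0

    control = arm(n_control, seed * 2 + 1, False)
    screened = arm(n_screened, seed * 2 + 2, True)
    return TrialResult(control=control, screened=screened)
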