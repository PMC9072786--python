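"""Screening tests, strategy schedules and the state edits screening makes.

A strategy is a declarative plan: which test is offered at which ages,
the participation probability per test type, and the referral rules.
Only two edits to the natural history are ever made, both requiring a
colonoscopy (primary or diagnostic): adenomas found are removed
(state returns to lesion-free) and preclinical cancer found becomes
*screen-detected* diagnosed cancer.  The one exception is the
sigmoidoscopy pathway, where a non-advanced adenoma is removed during
the sigmoidoscopy itself; only advanced adenomas or cancer trigger a
colonoscopy referral.

The eight standard strategies compared by the package (annual or
biennial stool testing over ages 50-69, short stool-testing programmes,
their combinations with colonoscopy, and one- or two-round colonoscopy
alone) are available from :func:`build_standard_scenario`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional

import numpy as np

from .engine import CompiledBundle, Individual, Stream, stream
from .params import HealthState, ParameterBundle, TestProfile

__all__ = [
    "Strategy",
    "ScreenOutcome",
    "test_outcome",
    "due_events",
    "apply_screening_round",
    "build_standard_scenario",
    "STANDARD_SCENARIO_LABELS",
]

FIT = "FIT"
COLONOSCOPY = "COLONOSCOPY"
SIGMOIDOSCOPY = "SIGMOIDOSCOPY"

#: Default real-world participation per test type (stool testing is far
#: better attended than invasive endoscopy).
DEFAULT_PARTICIPATION = {FIT: 0.94, COLONOSCOPY: 0.425, SIGMOIDOSCOPY: 1.0}

#: Stable integer codes keying the lifetime-attender random streams.
_TEST_CODE = {FIT: 0, COLONOSCOPY: 1, SIGMOIDOSCOPY: 2}


@dataclass(frozen=True)
class Strategy:
    """A declarative screening plan.

    ``events`` lists ``(age, test_name)`` offers.  A positive stool test
    leads to a diagnostic colonoscopy with probability
    ``colonoscopy_completion``; a sigmoidoscopy finding of an advanced
    adenoma or cancer leads to one with probability
    ``fs_colonoscopy_completion``.  After a negative *primary* screening
    colonoscopy, further scheduled colonoscopies are suppressed for
    ``rescreen_interval_after_negative_colonoscopy`` years.
    ``participation_model`` chooses between an independent attendance
    draw at every offer (``per_round``) and a single lifetime
    attender/never-attender draw per test type (``ever_attender``).
    """

    name: str
    events: tuple[tuple[int, str], ...] = ()
    participation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPATION)
    )
    colonoscopy_completion: float = 0.76
    fs_colonoscopy_completion: float = 0.96
    rescreen_interval_after_negative_colonoscopy: int = 10
    participation_model: Literal["per_round", "ever_attender"] = "per_round"

    def __post_init__(self):
        for age, test in self.events:
            if not 40 <= age < 80:
                raise ValueError(f"screening event age {age} outside [40, 80)")
        for test, p in self.participation.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"participation[{test}]={p} outside [0,1]")
        for nm, v in (
            ("colonoscopy_completion", self.colonoscopy_completion),
            ("fs_colonoscopy_completion", self.fs_colonoscopy_completion),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0,1]")
        if self.rescreen_interval_after_negative_colonoscopy <= 0:
            raise ValueError("rescreen interval must be positive")

    def participation_for(self, test_name: str) -> float:
        return float(self.participation.get(test_name, 1.0))

    def with_participation(self, **per_test: float) -> "Strategy":
        p = dict(self.participation)
        p.update(per_test)
        return replace(self, participation=p)


@dataclass
class ScreenOutcome:
    """What one screening offer did to one individual."""

    attended: bool = False
    test_result: Literal["positive", "negative", "not_done"] = "not_done"
    diagnostic_colonoscopy_done: bool = False
    lesion_removed: bool = False
    crc_detected: bool = False


def test_outcome(
    state: HealthState, profile: TestProfile, rng: np.random.Generator
) -> Literal["positive", "negative"]:
    """Draw one test result given the individual's true state."""
    if not state.is_undiagnosed:
        raise ValueError(f"screening test applied to state {state!r}")
    return "positive" if rng.random() < profile.positive_probability(state) else "negative"


def due_events(strategy: Strategy, individual: Individual) -> list[tuple[int, str]]:
    """Screening offers due at the individual's current age, honouring the
    post-negative-colonoscopy rescreen interval."""
    due = []
    for age, test in strategy.events:
        if age != individual.age:
            continue
        if (
            test == COLONOSCOPY
            and individual.next_colonoscopy_due_age is not None
            and age < individual.next_colonoscopy_due_age
        ):
            continue
        due.append((age, test))
    return due


def _colonoscopy_findings(
    state: HealthState, colo: TestProfile, rng: np.random.Generator
) -> tuple[HealthState, bool, bool]:
    """Resolve a colonoscopy: returns (new state, lesion_removed, crc_detected)."""
    detected = rng.random() < colo.positive_probability(state)
    if not detected:
        return state, False, False
    if state in (HealthState.NAA, HealthState.AA):
        return HealthState.NO_LESION, True, False
    if state == HealthState.PRECLINICAL_CRC:
        return HealthState.CRC_SCREEN_DETECTED, False, True
    return state, False, False  # false positive on a clean colon: no edit


def apply_screening_round(
    individual: Individual,
    event: tuple[int, str],
    strategy: Strategy,
    bundle: ParameterBundle,
    rng: np.random.Generator,
) -> ScreenOutcome:
    """Apply one screening offer to one individual, mutating it in place.

    Draw order per offer: participation, test result, referral
    completion (where applicable), colonoscopy detection.
    """
    age, test_name = event
    if not individual.alive or not individual.state.is_undiagnosed:
        raise ValueError("screening applies to alive, undiagnosed individuals")
    if test_name not in bundle.tests:
        raise KeyError(f"test {test_name!r} not in bundle")
    outcome = ScreenOutcome()

    if strategy.participation_model == "ever_attender":
        if individual.is_attender is None:
            individual.is_attender = rng.random() < strategy.participation_for(test_name)
        attends = individual.is_attender
    else:
        attends = rng.random() < strategy.participation_for(test_name)
    if not attends:
        return outcome
    outcome.attended = True

    profile = bundle.tests[test_name]
    result = test_outcome(individual.state, profile, rng)
    outcome.test_result = result

    colo = bundle.tests[COLONOSCOPY]
    if test_name == COLONOSCOPY:
        new_state, removed, crc = _colonoscopy_findings(individual.state, colo, rng)
        # a primary colonoscopy *is* the test: its result is the finding
        outcome.test_result = "positive" if (removed or crc) else "negative"
        if outcome.test_result == "negative":
            individual.next_colonoscopy_due_age = (
                age + strategy.rescreen_interval_after_negative_colonoscopy
            )
        individual.state, outcome.lesion_removed, outcome.crc_detected = new_state, removed, crc
    elif test_name == FIT:
        if result == "positive":
            if rng.random() < strategy.colonoscopy_completion:
                outcome.diagnostic_colonoscopy_done = True
                new_state, removed, crc = _colonoscopy_findings(individual.state, colo, rng)
                individual.state = new_state
                outcome.lesion_removed, outcome.crc_detected = removed, crc
    elif test_name == SIGMOIDOSCOPY:
        if result == "positive":
            if individual.state == HealthState.NAA:
                # small adenomas are snared during the sigmoidoscopy itself
                individual.state = HealthState.NO_LESION
                outcome.lesion_removed = True
            elif individual.state in (HealthState.AA, HealthState.PRECLINICAL_CRC):
                if rng.random() < strategy.fs_colonoscopy_completion:
                    outcome.diagnostic_colonoscopy_done = True
                    new_state, removed, crc = _colonoscopy_findings(
                        individual.state, colo, rng
                    )
                    individual.state = new_state
                    outcome.lesion_removed, outcome.crc_detected = removed, crc
    else:
        raise KeyError(f"unknown test {test_name!r}")

    if outcome.crc_detected:
        individual.years_since_dx = 0
    return outcome


# ---------------------------------------------------------------------------
# vectorized engine hook
# ---------------------------------------------------------------------------


def screen_cohort_event(
    *,
    state: np.ndarray,
    sex_idx: np.ndarray,
    ysd: np.ndarray,
    next_colo_due: np.ndarray,
    attender: dict,
    age: int,
    test_name: str,
    strategy: Strategy,
    compiled: CompiledBundle,
    seed: int,
    cycle: int,
    event_index: int,
    offer_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized equivalent of :func:`apply_screening_round` for one
    scheduled offer; mutates the cohort arrays and returns the mask of
    newly screen-detected cancers.

    Random draws come from purpose-keyed streams indexed by
    ``(cycle, event_index)`` and are positionally aligned across runs, so
    strategies sharing a seed share participation and test noise (common
    random numbers).
    """
    bundle = compiled.bundle
    if test_name not in bundle.tests:
        raise KeyError(f"test {test_name!r} not in bundle")
    profile = bundle.tests[test_name]
    colo = bundle.tests[COLONOSCOPY]
    n = state.shape[0]

    eligible = state <= HealthState.PRECLINICAL_CRC
    if offer_mask is not None:
        eligible &= offer_mask
    if test_name == COLONOSCOPY:
        eligible &= ~((next_colo_due >= 0) & (age < next_colo_due))

    if strategy.participation_model == "ever_attender":
        if test_name not in attender:
            u = stream(seed, Stream.EVER_ATTENDER, _TEST_CODE[test_name]).random(n)
            attender[test_name] = u < strategy.participation_for(test_name)
        attends = eligible & attender[test_name]
    else:
        u = stream(seed, Stream.SCREEN_PARTICIPATION, cycle, event_index).random(n)
        attends = eligible & (u < strategy.participation_for(test_name))

    u_test = stream(seed, Stream.SCREEN_TEST, cycle, event_index).random(n)
    p_pos = profile.positive_prob_by_state()[np.clip(state, 0, 3)]
    positive = attends & (u_test < p_pos)

    u_refer = stream(seed, Stream.SCREEN_REFERRAL, cycle, event_index).random(n)
    u_colo = stream(seed, Stream.SCREEN_COLONOSCOPY, cycle, event_index).random(n)
    colo_detect = u_colo < colo.positive_prob_by_state()[np.clip(state, 0, 3)]

    removed = np.zeros(n, dtype=bool)
    crc_found = np.zeros(n, dtype=bool)

    if test_name == COLONOSCOPY:
        scoped = attends & colo_detect  # the primary test's own detection draw
        removed = scoped & ((state == HealthState.NAA) | (state == HealthState.AA))
        crc_found = scoped & (state == HealthState.PRECLINICAL_CRC)
        negative = attends & ~(removed | crc_found)
        next_colo_due[negative] = age + strategy.rescreen_interval_after_negative_colonoscopy
    elif test_name == FIT:
        referred = positive & (u_refer < strategy.colonoscopy_completion)
        scoped = referred & colo_detect
        removed = scoped & ((state == HealthState.NAA) | (state == HealthState.AA))
        crc_found = scoped & (state == HealthState.PRECLINICAL_CRC)
    elif test_name == SIGMOIDOSCOPY:
        removed = positive & (state == HealthState.NAA)
        advanced = positive & (
            (state == HealthState.AA) | (state == HealthState.PRECLINICAL_CRC)
        )
        referred = advanced & (u_refer < strategy.fs_colonoscopy_completion)
        scoped = referred & colo_detect
        removed |= scoped & (state == HealthState.AA)
        crc_found = scoped & (state == HealthState.PRECLINICAL_CRC)
    else:
        raise KeyError(f"unknown test {test_name!r}")

    state[removed] = HealthState.NO_LESION
    state[crc_found] = HealthState.CRC_SCREEN_DETECTED
    ysd[crc_found] = 0
    return crc_found


# ---------------------------------------------------------------------------
# the 8 standard comparison strategies
# ---------------------------------------------------------------------------

STANDARD_SCENARIO_LABELS = {
    1: "no screening",
    2: "annual FIT, ages 50-69",
    3: "biennial FIT, ages 50-69",
    4: "annual FIT, ages 50-54",
    5: "three FITs at 50, 52, 54",
    6: "annual FIT 50-54 + colonoscopy at 55 and 65",
    7: "three FITs at 50, 52, 54 + colonoscopy at 55 and 65",
    8: "colonoscopy at 50 and 60",
}


def build_standard_scenario(scenario_id: int, **overrides) -> Strategy:
    """Return one of the 8 standard screening strategies by id.

    Keyword overrides are forwarded to the :class:`Strategy` constructor
    (e.g. ``participation={...}`` for sensitivity analyses).
    """
    fit = lambda ages: tuple((a, FIT) for a in ages)
    colo = lambda ages: tuple((a, COLONOSCOPY) for a in ages)
    schedules = {
        1: (),
        2: fit(range(50, 70)),
        3: fit(range(50, 70, 2)),
        4: fit(range(50, 55)),
        5: fit((50, 52, 54)),
        6: fit(range(50, 55)) + colo((55, 65)),
        7: fit((50, 52, 54)) + colo((55, 65)),
        8: colo((50, 60)),
    }
    if scenario_id not in schedules:
        raise ValueError(f"unknown scenario id {scenario_id!r}; expected 1..8")
    kwargs = dict(
        name=f"scenario_{scenario_id}",
        events=schedules[scenario_id],
    )
    kwargs.update(overrides)
    return Strategy(**kwargs)
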