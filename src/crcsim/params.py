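"""Parameter model for the colorectal-cancer natural-history simulation.

The simulation follows the adenoma-carcinoma sequence: normal mucosa can
develop a non-advanced adenoma (NAA), which can progress to an advanced
adenoma (AA), then to preclinical (asymptomatic, screen-detectable)
cancer, and finally to clinically diagnosed cancer.  All parameters are
annual probabilities on a 1-year simulation cycle.

This module defines the typed containers for every probability the model
consumes (initial state prevalence at age 40, sex/age-band transition
probabilities, a life table, a 5-year cancer-survival profile, screening
test operating characteristics), the closed-form probability formulas
shared by the engine, and bundle validation / CSV+YAML round-trip I/O.
The on-disk column layout is documented in ``docs/bundle_schema.md``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HealthState",
    "SEXES",
    "InitialPrevalence",
    "TransitionTable",
    "LifeTable",
    "CRCSurvivalProfile",
    "TestProfile",
    "ParameterBundle",
    "BundleValidationError",
    "non_crc_death_probability",
    "crc_hazard_adjustment_factor",
    "adjust_annual_crc_death_probability",
    "age_band_of",
    "load_parameter_bundle",
    "save_parameter_bundle",
]

SEXES = ("male", "female")

#: Ordered names of the four forward transitions of the adenoma-carcinoma
#: sequence; the index doubles as the originating state's code.
TRANSITION_FIELDS = (
    "p_norm_to_naa",
    "p_naa_to_aa",
    "p_aa_to_preclin",
    "p_preclin_to_clinical",
)

AGE_MIN = 40
AGE_MAX = 80


class HealthState(enum.IntEnum):
    """Health states of one individual.

    The integer codes order the undiagnosed states by severity, which the
    engine exploits: natural progression only ever increments the code.
    The two diagnosed-cancer codes distinguish the mode of detection
    (screening versus symptoms); both death states are absorbing.
    """

    NO_LESION = 0
    NAA = 1
    AA = 2
    PRECLINICAL_CRC = 3
    CRC_SCREEN_DETECTED = 4
    CRC_SYMPTOM_DETECTED = 5
    DEATH_CRC = 6
    DEATH_OTHER = 7

    @property
    def is_undiagnosed(self) -> bool:
        return self <= HealthState.PRECLINICAL_CRC

    @property
    def is_diagnosed_crc(self) -> bool:
        return self in (HealthState.CRC_SCREEN_DETECTED, HealthState.CRC_SYMPTOM_DETECTED)

    @property
    def is_dead(self) -> bool:
        return self >= HealthState.DEATH_CRC


UNDIAGNOSED_STATES = tuple(s for s in HealthState if s.is_undiagnosed)


# ---------------------------------------------------------------------------
# closed-form probability formulas
# ---------------------------------------------------------------------------

def non_crc_death_probability(p_all_cause: float, p_crc: float) -> float:
    """Annual probability of death from causes other than colorectal cancer.

    Derived from a life table by removing the cancer-specific component on
    the hazard scale: ``1 - exp(-(p_all_cause - p_crc))``.  Treating the
    annual probabilities as (approximate) hazards keeps the result a valid
    probability for any consistent life-table row.
    """
    if not (0.0 <= p_crc <= p_all_cause <= 1.0):
        raise ValueError(
            f"inconsistent life-table row: need 0 <= p_crc <= p_all_cause <= 1, "
            f"got p_all_cause={p_all_cause!r}, p_crc={p_crc!r}"
        )
    return -math.expm1(-(p_all_cause - p_crc))


def crc_hazard_adjustment_factor(s5_source: float, s5_target: float) -> float:
    """Proportional-hazards factor mapping source-population cancer survival
    onto the target population.

    ``k = ln(s5_target) / ln(s5_source)``: scaling the cumulative death
    hazard by ``k`` turns a 5-year survival of ``s5_source`` into exactly
    ``s5_target``.  ``k > 1`` when the target population fares worse.
    """
    for name, s in (("s5_source", s5_source), ("s5_target", s5_target)):
        if not (0.0 < s < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {s!r}")
    return math.log(s5_target) / math.log(s5_source)


def adjust_annual_crc_death_probability(q: float, k: float) -> float:
    """Apply a proportional-hazards factor ``k`` to an annual death
    probability: ``1 - (1 - q)**k``.

    Equivalent to multiplying the discrete hazard ``-ln(1-q)`` by ``k``;
    preserves the [0, 1] range and is the identity at ``k = 1``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be a probability, got {q!r}")
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k!r}")
    return -math.expm1(k * math.log1p(-q)) if q < 1.0 else 1.0


# ---------------------------------------------------------------------------
# typed parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InitialPrevalence:
    """State distribution at age 40 for one sex (diagnosed cancer and death
    start at zero prevalence)."""

    sex: str
    no_lesion: float
    naa: float
    aa: float
    preclinical_crc: float

    def fractions(self) -> np.ndarray:
        return np.array([self.no_lesion, self.naa, self.aa, self.preclinical_crc])

    def validate(self) -> list[str]:
        errors = []
        if self.sex not in SEXES:
            errors.append(f"initial_prevalence: unknown sex {self.sex!r}")
        fr = self.fractions()
        if ((fr < 0) | (fr > 1)).any():
            errors.append(f"initial_prevalence[{self.sex}]: fractions outside [0,1]: {fr}")
        if abs(fr.sum() - 1.0) > 1e-9:
            errors.append(
                f"initial_prevalence[{self.sex}]: fractions sum to {fr.sum():.12f}, not 1"
            )
        return errors


@dataclass(frozen=True)
class TransitionTable:
    """Annual forward-transition probabilities by sex and age band.

    ``bands`` is a sorted tuple of closed-open ``(lo, hi)`` intervals that
    must partition [40, 80); ``probs`` maps sex to an array of shape
    ``(n_bands, 4)`` in :data:`TRANSITION_FIELDS` order.
    """

    bands: tuple[tuple[int, int], ...]
    probs: Mapping[str, np.ndarray]

    def validate(self) -> list[str]:
        errors = []
        cursor = AGE_MIN
        for lo, hi in self.bands:
            if lo != cursor:
                errors.append(
                    f"transitions: band gap/overlap at age {cursor} (next band starts {lo})"
                )
            cursor = hi
        if cursor != AGE_MAX:
            errors.append(f"transitions: bands end at {cursor}, expected {AGE_MAX}")
        for sex in SEXES:
            if sex not in self.probs:
                errors.append(f"transitions: missing sex {sex!r}")
                continue
            p = np.asarray(self.probs[sex], dtype=float)
            if p.shape != (len(self.bands), len(TRANSITION_FIELDS)):
                errors.append(
                    f"transitions[{sex}]: shape {p.shape}, expected "
                    f"{(len(self.bands), len(TRANSITION_FIELDS))}"
                )
                continue
            if ((p < 0) | (p > 1)).any():
                errors.append(f"transitions[{sex}]: probabilities outside [0,1]")
        return errors

    def band_index_of(self, age: float) -> int:
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= age < hi:
                return i
        raise ValueError(f"age {age} outside transition-table coverage [40, 80)")

    def probability(self, sex: str, age: float, transition: str) -> float:
        j = TRANSITION_FIELDS.index(transition)
        return float(self.probs[sex][self.band_index_of(age), j])

    def by_age(self, sex: str) -> np.ndarray:
        """Expand bands to a dense ``(40, 4)`` array over integer ages 40..79."""
        out = np.empty((AGE_MAX - AGE_MIN, len(TRANSITION_FIELDS)))
        for i, (lo, hi) in enumerate(self.bands):
            out[lo - AGE_MIN : hi - AGE_MIN] = self.probs[sex][i]
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for i, (lo, hi) in enumerate(self.bands):
                row = {"sex": sex, "age_lo": lo, "age_hi": hi}
                row.update(
                    {f: float(self.probs[sex][i, j]) for j, f in enumerate(TRANSITION_FIELDS)}
                )
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionTable":
        bands = sorted({(int(r.age_lo), int(r.age_hi)) for r in df.itertuples()})
        probs = {}
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age_lo")
            probs[str(sex)] = grp[list(TRANSITION_FIELDS)].to_numpy(dtype=float)
        return cls(bands=tuple(bands), probs=probs)


def age_band_of(age: float, transitions: TransitionTable) -> tuple[int, int]:
    """Return the closed-open ``(lo, hi)`` band of ``transitions`` containing
    ``age``; bands follow the ``lo <= age < hi`` convention."""
    return transitions.bands[transitions.band_index_of(age)]


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause and cancer-specific mortality by sex and single age.

    Covers integer ages 40..80; rows must satisfy ``p_crc <= p_all_cause``
    so the competing non-cancer death probability is well defined.
    """

    ages: np.ndarray  # integer ages, 40..80 inclusive
    p_all_cause: Mapping[str, np.ndarray]
    p_crc: Mapping[str, np.ndarray]

    def validate(self) -> list[str]:
        errors = []
        expected = np.arange(AGE_MIN, AGE_MAX + 1)
        if not np.array_equal(np.asarray(self.ages), expected):
            errors.append(
                f"life_table: ages must cover {AGE_MIN}..{AGE_MAX}; got "
                f"{np.asarray(self.ages).min(initial=-1)}..{np.asarray(self.ages).max(initial=-1)}"
            )
            return errors
        for sex in SEXES:
            if sex not in self.p_all_cause or sex not in self.p_crc:
                errors.append(f"life_table: missing sex {sex!r}")
                continue
            pa = np.asarray(self.p_all_cause[sex], dtype=float)
            pc = np.asarray(self.p_crc[sex], dtype=float)
            bad = np.flatnonzero(~((0 <= pc) & (pc <= pa) & (pa <= 1)))
            for i in bad:
                errors.append(
                    f"life_table[{sex}, age {int(self.ages[i])}]: need "
                    f"0 <= p_crc <= p_all_cause <= 1, got p_crc={pc[i]:.6g}, "
                    f"p_all_cause={pa[i]:.6g}"
                )
        return errors

    def non_crc_death(self, sex: str) -> np.ndarray:
        """Dense array of annual non-cancer death probabilities, ages 40..80."""
        pa = np.asarray(self.p_all_cause[sex], dtype=float)
        pc = np.asarray(self.p_crc[sex], dtype=float)
        return -np.expm1(-(pa - pc))

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for i, age in enumerate(self.ages):
                rows.append(
                    {
                        "sex": sex,
                        "age": int(age),
                        "p_all_cause": float(self.p_all_cause[sex][i]),
                        "p_crc": float(self.p_crc[sex][i]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        ages = np.sort(df["age"].unique())
        p_all, p_crc = {}, {}
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            p_all[str(sex)] = grp["p_all_cause"].to_numpy(dtype=float)
            p_crc[str(sex)] = grp["p_crc"].to_numpy(dtype=float)
        return cls(ages=ages, p_all_cause=p_all, p_crc=p_crc)


@dataclass(frozen=True)
class CRCSurvivalProfile:
    """Annual cancer-death probabilities for the first five years after
    diagnosis, plus the survival adjustment between populations.

    ``q`` holds the unadjusted probabilities q1..q5 indexed by year since
    diagnosis; patients alive more than 5 years after diagnosis are treated
    as cured (zero cancer-specific hazard thereafter).  The profile is
    rescaled on the hazard scale so the implied 5-year survival moves from
    ``s5_source`` (the population the q's were estimated in) to
    ``s5_target``.  Screen-detected cancers receive an additional hazard
    multiplier (< 1 encodes a survival advantage of earlier detection).
    """

    q: tuple[float, float, float, float, float]
    s5_source: float
    s5_target: float
    screen_detected_hazard_multiplier: float = 0.7

    def validate(self) -> list[str]:
        errors = []
        if len(self.q) != 5:
            errors.append(f"crc_survival: need exactly 5 annual probabilities, got {len(self.q)}")
        if any(not (0.0 <= qi <= 1.0) for qi in self.q):
            errors.append(f"crc_survival: q outside [0,1]: {self.q}")
        for name, s in (("s5_source", self.s5_source), ("s5_target", self.s5_target)):
            if not (0.0 < s < 1.0):
                errors.append(f"crc_survival: {name} must lie in (0,1), got {s}")
        if self.screen_detected_hazard_multiplier <= 0:
            errors.append(
                "crc_survival: screen_detected_hazard_multiplier must be positive, got "
                f"{self.screen_detected_hazard_multiplier}"
            )
        return errors

    @property
    def adjustment_factor(self) -> float:
        return crc_hazard_adjustment_factor(self.s5_source, self.s5_target)

    def adjusted_q(self, screen_detected: bool = False) -> np.ndarray:
        """Population-adjusted annual death probabilities q1..q5, with the
        extra detection-mode multiplier folded in for screen-detected cases."""
        k = self.adjustment_factor
        if screen_detected:
            k *= self.screen_detected_hazard_multiplier
        return np.array([adjust_annual_crc_death_probability(qi, k) for qi in self.q])

    def five_year_survival(self, adjusted: bool = True, screen_detected: bool = False) -> float:
        q = self.adjusted_q(screen_detected) if adjusted else np.asarray(self.q)
        return float(np.prod(1.0 - q))


@dataclass(frozen=True)
class TestProfile:
    """Operating characteristics of one screening test: per-lesion-class
    sensitivity plus specificity against a lesion-free colon."""

    name: str
    sensitivity_naa: float
    sensitivity_aa: float
    sensitivity_crc: float
    specificity: float

    def validate(self) -> list[str]:
        errors = []
        for f in ("sensitivity_naa", "sensitivity_aa", "sensitivity_crc", "specificity"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                errors.append(f"test[{self.name}].{f}: {v} outside [0,1]")
        return errors

    def positive_probability(self, state: HealthState) -> float:
        """Probability of a positive result given the individual's true
        (undiagnosed) state."""
        if state == HealthState.NO_LESION:
            return 1.0 - self.specificity
        if state == HealthState.NAA:
            return self.sensitivity_naa
        if state == HealthState.AA:
            return self.sensitivity_aa
        if state == HealthState.PRECLINICAL_CRC:
            return self.sensitivity_crc
        raise ValueError(f"test applied to non-screenable state {state!r}")

    def positive_prob_by_state(self) -> np.ndarray:
        """Vector of positive probabilities indexed by state code 0..3."""
        return np.array(
            [
                1.0 - self.specificity,
                self.sensitivity_naa,
                self.sensitivity_aa,
                self.sensitivity_crc,
            ]
        )


class BundleValidationError(ValueError):
    """Raised when a parameter bundle violates one or more invariants; the
    message enumerates every violation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid parameter bundle:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class ParameterBundle:
    """Everything the simulation consumes, validated as a unit."""

    initial_prevalence: Mapping[str, InitialPrevalence]
    transitions: TransitionTable
    life_table: LifeTable
    crc_survival: CRCSurvivalProfile
    tests: Mapping[str, TestProfile]
    sex_ratio_at_entry: float = 0.5

    def collect_errors(self) -> list[str]:
        errors: list[str] = []
        for sex in SEXES:
            if sex not in self.initial_prevalence:
                errors.append(f"initial_prevalence: missing sex {sex!r}")
            else:
                errors.extend(self.initial_prevalence[sex].validate())
        errors.extend(self.transitions.validate())
        errors.extend(self.life_table.validate())
        errors.extend(self.crc_survival.validate())
        for t in self.tests.values():
            errors.extend(t.validate())
        if not (0.0 <= self.sex_ratio_at_entry <= 1.0):
            errors.append(f"sex_ratio_at_entry outside [0,1]: {self.sex_ratio_at_entry}")
        return errors

    def validate(self) -> "ParameterBundle":
        errors = self.collect_errors()
        if errors:
            raise BundleValidationError(errors)
        return self

    def with_transitions(self, transitions: TransitionTable) -> "ParameterBundle":
        return replace(self, transitions=transitions)


# ---------------------------------------------------------------------------
# bundle I/O: a directory of CSV tables plus a YAML config
# ---------------------------------------------------------------------------

_FILES = {
    "initial_prevalence": "initial_prevalence.csv",
    "transitions": "transitions.csv",
    "life_table": "life_table.csv",
    "config": "config.yaml",
}


def save_parameter_bundle(bundle: ParameterBundle, path: str | Path) -> Path:
    """Write ``bundle`` to ``path`` (a directory) as CSV tables + config.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ip_rows = [
        {
            "sex": p.sex,
            "no_lesion": p.no_lesion,
            "naa": p.naa,
            "aa": p.aa,
            "preclinical_crc": p.preclinical_crc,
        }
        for p in (bundle.initial_prevalence[s] for s in SEXES)
    ]
    pd.DataFrame(ip_rows).to_csv(path / _FILES["initial_prevalence"], index=False)
    bundle.transitions.as_frame().to_csv(path / _FILES["transitions"], index=False)
    bundle.life_table.as_frame().to_csv(path / _FILES["life_table"], index=False)
    config = {
        "sex_ratio_at_entry": bundle.sex_ratio_at_entry,
        "crc_survival": {
            "q": [float(x) for x in bundle.crc_survival.q],
            "s5_source": bundle.crc_survival.s5_source,
            "s5_target": bundle.crc_survival.s5_target,
            "screen_detected_hazard_multiplier": bundle.crc_survival.screen_detected_hazard_multiplier,
        },
        "tests": {
            name: {
                "sensitivity_naa": t.sensitivity_naa,
                "sensitivity_aa": t.sensitivity_aa,
                "sensitivity_crc": t.sensitivity_crc,
                "specificity": t.specificity,
            }
            for name, t in bundle.tests.items()
        },
    }
    with open(path / _FILES["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def load_parameter_bundle(path: str | Path) -> ParameterBundle:
    """Load and validate a bundle directory written by
    :func:`save_parameter_bundle`.

    All invariant violations are collected and reported together in the
    raised :class:`BundleValidationError`, not just the first one found.
    """
    path = Path(path)
    errors: list[str] = []
    missing = [f for f in _FILES.values() if not (path / f).exists()]
    if missing:
        raise BundleValidationError([f"missing bundle file: {m}" for m in missing])

    ip_df = pd.read_csv(path / _FILES["initial_prevalence"])
    initial = {
        str(r.sex): InitialPrevalence(
            sex=str(r.sex),
            no_lesion=float(r.no_lesion),
            naa=float(r.naa),
            aa=float(r.aa),
            preclinical_crc=float(r.preclinical_crc),
        )
        for r in ip_df.itertuples()
    }
    transitions = TransitionTable.from_frame(pd.read_csv(path / _FILES["transitions"]))
    life = LifeTable.from_frame(pd.read_csv(path / _FILES["life_table"]))
    with open(path / _FILES["config"]) as fh:
        config = yaml.safe_load(fh)
    surv = config["crc_survival"]
    crc_survival = CRCSurvivalProfile(
        q=tuple(float(x) for x in surv["q"]),
        s5_source=float(surv["s5_source"]),
        s5_target=float(surv["s5_target"]),
        screen_detected_hazard_multiplier=float(
            surv.get("screen_detected_hazard_multiplier", 0.7)
        ),
    )
    tests = {
        name: TestProfile(name=name, **{k: float(v) for k, v in spec.items()})
        for name, spec in config.get("tests", {}).items()
    }
    bundle = ParameterBundle(
        initial_prevalence=initial,
        transitions=transitions,
        life_table=life,
        crc_survival=crc_survival,
        tests=tests,
        sex_ratio_at_entry=float(config.get("sex_ratio_at_entry", 0.5)),
    )
    errors.extend(bundle.collect_errors())
    if errors:
        raise BundleValidationError(errors)
    return bundle
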