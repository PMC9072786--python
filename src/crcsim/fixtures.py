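"""Synthetic parameter generation.

The exact calibrated transition probabilities and source life tables the
package's default analyses emulate are not redistributable, so this
module generates every input programmatically: a Gompertz-shaped life
table, a default parameter bundle whose no-screening cohort reproduces a
plausible Chinese age-specific colorectal-cancer incidence/mortality
schedule (rising from roughly 13 to roughly 86 diagnoses per 100,000
person-years between ages 40 and 80), and calibration-target sets with
known ground truth for parameter-recovery experiments.

Everything here is deterministic given ``(spec, seed)`` and needs no
network access or external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import calibration as _calibration
from .engine import run_cohort
from .params import (
    AGE_MAX,
    AGE_MIN,
    SEXES,
    CRCSurvivalProfile,
    InitialPrevalence,
    LifeTable,
    ParameterBundle,
    TestProfile,
    TransitionTable,
)

__all__ = [
    "FixtureSpec",
    "synth_life_table",
    "default_parameter_set",
    "synth_calibration_targets",
]

#: Screening test operating characteristics installed verbatim in every
#: generated bundle: stool-test sensitivities for non-advanced adenoma,
#: advanced adenoma and cancer with specificity 0.95; sigmoidoscopy
#: sensitivities 0.59 (adenoma) / 0.61 (cancer) with specificity 0.92;
#: colonoscopy treated as a near-perfect reference standard.
DEFAULT_TESTS = {
    "FIT": dict(sensitivity_naa=0.05, sensitivity_aa=0.26, sensitivity_crc=0.76, specificity=0.95),
    "SIGMOIDOSCOPY": dict(
        sensitivity_naa=0.59, sensitivity_aa=0.59, sensitivity_crc=0.61, specificity=0.92
    ),
    "COLONOSCOPY": dict(
        sensitivity_naa=0.95, sensitivity_aa=0.95, sensitivity_crc=0.95, specificity=1.0
    ),
}

#: Five-year relative survival after a cancer diagnosis: the population
#: the annual death probabilities were estimated in (0.622) versus the
#: population being modelled (0.527).
S5_SOURCE = 0.622
S5_TARGET = 0.527


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters for synthetic inputs.

    Mortality is Gompertz: annual all-cause probability
    ``baseline * exp(slope * (age - 40))`` per sex, with the
    cancer-specific component following its own (steeper) exponential.
    ``onset_level`` scales adenoma onset, ``progression_level`` scales
    the adenoma-to-cancer steps; both default to 1 (the tuned shape).
    ``target_noise`` is the calibration-target CI half-width as a
    fraction of the target value.
    """

    seed: int = 0
    mortality_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.0022, "female": 0.0014}
    )
    mortality_slope: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.085, "female": 0.088}
    )
    crc_mortality_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"male": 5e-6, "female": 3.5e-6}
    )
    crc_mortality_slope: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.115, "female": 0.112}
    )
    onset_level: float = 1.0
    progression_level: float = 1.0
    target_noise: float = 0.1


def synth_life_table(spec: FixtureSpec) -> LifeTable:
    """Gompertz life table over ages 40..80 for both sexes."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    p_all, p_crc = {}, {}
    for sex in SEXES:
        pa = spec.mortality_baseline[sex] * np.exp(spec.mortality_slope[sex] * (ages - AGE_MIN))
        pc = spec.crc_mortality_baseline[sex] * np.exp(
            spec.crc_mortality_slope[sex] * (ages - AGE_MIN)
        )
        if pa.max() > 1.0:
            raise ValueError(
                f"mortality shape for {sex} exceeds probability 1 at age "
                f"{ages[int(np.argmax(pa > 1.0))]}"
            )
        p_all[sex] = pa
        p_crc[sex] = np.minimum(pc, pa)  # keep rows consistent by construction
    return LifeTable(ages=ages, p_all_cause=p_all, p_crc=p_crc)


# Tuned per-band annual transition probabilities (bands [40,50), [50,60),
# [60,70), [70,80); columns: lesion onset, NAA->AA, AA->preclinical,
# preclinical->clinical).  The shape was chosen so the no-screening
# cohort's 5-year-window diagnosis rate rises from about 13 to about 86
# per 100,000 person-years between ages 40 and 80, with men roughly 1.3x
# women — a plausible Chinese schedule.
_BASE_TRANSITIONS = {
    "male": np.array(
        [
            [0.0090, 0.0060, 0.0130, 0.25],
            [0.0100, 0.0060, 0.0150, 0.25],
            [0.0110, 0.0070, 0.0190, 0.25],
            [0.0120, 0.0080, 0.0190, 0.25],
        ]
    ),
    "female": np.array(
        [
            [0.0070, 0.0045, 0.0110, 0.25],
            [0.0080, 0.0050, 0.0125, 0.25],
            [0.0090, 0.0060, 0.0155, 0.25],
            [0.0100, 0.0070, 0.0155, 0.25],
        ]
    ),
}

_BANDS = ((40, 50), (50, 60), (60, 70), (70, 80))

_INITIAL_PREVALENCE = {
    "male": dict(naa=0.145, aa=0.026, preclinical_crc=0.00070),
    "female": dict(naa=0.095, aa=0.017, preclinical_crc=0.00042),
}


def _default_transitions(spec: FixtureSpec) -> TransitionTable:
    probs = {}
    for sex in SEXES:
        p = _BASE_TRANSITIONS[sex].copy()
        p[:, 0] *= spec.onset_level
        p[:, 1:3] *= spec.progression_level
        probs[sex] = np.clip(p, 0.0, 1.0)
    return TransitionTable(bands=_BANDS, probs=probs)


def _default_survival() -> CRCSurvivalProfile:
    # q5 solved so the unadjusted profile implies the source population's
    # 5-year survival exactly; the hazard-power adjustment then hits the
    # target population's survival to machine precision.
    q123 = (0.17, 0.11, 0.07, 0.05)
    q5 = 1.0 - S5_SOURCE / np.prod([1.0 - q for q in q123])
    return CRCSurvivalProfile(
        q=(*q123, float(q5)),
        s5_source=S5_SOURCE,
        s5_target=S5_TARGET,
        screen_detected_hazard_multiplier=0.7,
    )


def default_parameter_set(seed: int = 0, spec: FixtureSpec | None = None) -> ParameterBundle:
    """The package's default synthetic parameter bundle.

    Natural-history parameters follow the tuned plausible-China shape;
    the screening-test table is installed verbatim from
    :data:`DEFAULT_TESTS`.  Deterministic: the seed only tags the spec.
    """
    spec = spec or FixtureSpec(seed=seed)
    initial = {
        sex: InitialPrevalence(
            sex=sex,
            no_lesion=1.0 - sum(_INITIAL_PREVALENCE[sex].values()),
            **_INITIAL_PREVALENCE[sex],
        )
        for sex in SEXES
    }
    bundle = ParameterBundle(
        initial_prevalence=initial,
        transitions=_default_transitions(spec),
        life_table=synth_life_table(spec),
        crc_survival=_default_survival(),
        tests={name: TestProfile(name=name, **kw) for name, kw in DEFAULT_TESTS.items()},
        sex_ratio_at_entry=0.5,
    )
    return bundle.validate()


def synth_calibration_targets(
    true_bundle: ParameterBundle,
    n: int,
    noise: float,
    seed: int,
    bands: Sequence[tuple[int, int]] | None = None,
    quantities: Sequence[str] | None = None,
) -> list["_calibration.CalibrationTarget"]:
    """Simulate ``true_bundle`` and turn its band summaries into
    calibration targets with known ground truth.

    CI half-widths are ``max(noise * value, 3 * MC standard error)``; at
    ``noise = 0`` the targets sit exactly on the model summary for the
    same ``(n, seed)``, enabling exact-recovery experiments under common
    random numbers.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    summaries = _calibration.model_summaries(
        true_bundle, n=n, seed=seed, bands=bands, quantities=quantities
    )
    targets = []
    for key, value in summaries.items():
        quantity, sex, lo, hi = key
        mc_se = _mc_standard_error(quantity, value, n)
        half = max(noise * value, 3.0 * mc_se)
        if half == 0.0:
            half = max(1e-6, 3.0 * mc_se)
        targets.append(
            _calibration.CalibrationTarget(
                quantity=quantity,
                sex=sex,
                age_lo=lo,
                age_hi=hi,
                value=value,
                ci_low=max(0.0, value - half),
                ci_high=value + half,
            )
        )
    return targets


def _mc_standard_error(quantity: str, value: float, n: int) -> float:
    """Rough binomial/Poisson Monte-Carlo standard error for a summary."""
    if quantity.startswith("prevalence"):
        p = min(max(value, 1e-9), 1 - 1e-9)
        return float(np.sqrt(p * (1 - p) / max(n // 2, 1)))
    # rates per 100,000 person-years; exposure per band is at most n * width
    events = max(value * n / 1e5, 1e-9)
    return float(value / np.sqrt(events)) if events > 0 else 0.0
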