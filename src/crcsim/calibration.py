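"""Calibration of natural-history parameters and model-vs-registry
agreement statistics.

The workflow mirrors how state-transition cancer models are calibrated
in practice: simulate a no-screening cohort, summarise lesion prevalence
and cancer incidence/mortality by sex and age band, score the summaries
against observed targets (squared deviations standardised by the target
CI half-width), and search the free parameters with a Latin-hypercube
screen followed by coordinate-wise quadratic refinement.  Agreement with
registry rates is expressed as rate ratios pooled by random-effects
meta-analysis (DerSimonian-Laird) and tested for equivalence with two
one-sided tests (TOST) at a configurable margin, conventionally 20%
(rate ratio within [0.8, 1.2]).

All simulation-based evaluations share a fixed simulation seed (common
random numbers), so the calibration objective is a deterministic
function of the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .engine import CohortResult, run_cohort
from .params import (
    AGE_MAX,
    AGE_MIN,
    SEXES,
    HealthState,
    ParameterBundle,
    TransitionTable,
    TRANSITION_FIELDS,
)

__all__ = [
    "CalibrationTarget",
    "TOSTResult",
    "model_summaries",
    "calibration_objective",
    "calibrate",
    "rate_ratio_ci",
    "tost_equivalence",
    "ci_coverage_count",
    "apply_free_parameters",
]

DEFAULT_QUANTITIES = (
    "prevalence_naa",
    "prevalence_aa",
    "prevalence_crc",
    "prevalence_any_advanced",
    "incidence",
    "mortality",
)


@dataclass(frozen=True)
class CalibrationTarget:
    """One observed epidemiological quantity with its 95% CI.

    Prevalences are proportions among the alive population at the band
    midpoint age; incidence and mortality are rates per 100,000
    person-years over the band.  ``sex`` may be ``"male"``, ``"female"``
    or ``"both"``.
    """

    quantity: str
    sex: str
    age_lo: int
    age_hi: int
    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"target {self.key()}: need ci_low <= value <= ci_high, got "
                f"({self.ci_low}, {self.value}, {self.ci_high})"
            )
        if self.value < 0 or self.ci_low < 0:
            raise ValueError(f"target {self.key()}: negative value/CI")

    def key(self) -> tuple:
        return (self.quantity, self.sex, self.age_lo, self.age_hi)

    @property
    def half_width(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0


@dataclass(frozen=True)
class TOSTResult:
    """Output of the two-one-sided-tests equivalence procedure on a
    pooled rate ratio."""

    rate_ratio: float
    ci_low: float
    ci_high: float
    p_lower: float
    p_upper: float
    margin: float
    equivalent: bool
    tau2: float = 0.0
    warning: str | None = None


# ---------------------------------------------------------------------------
# model summaries and the objective
# ---------------------------------------------------------------------------


def _sex_slice(sex: str) -> list[int]:
    if sex == "both":
        return [0, 1]
    return [SEXES.index(sex)]


def summaries_from_result(
    result: CohortResult,
    bands: Sequence[tuple[int, int]] | None = None,
    quantities: Sequence[str] | None = None,
    sexes: Sequence[str] = ("male", "female"),
) -> dict[tuple, float]:
    """Band summaries keyed ``(quantity, sex, age_lo, age_hi)`` from a
    finished cohort run.

    Prevalence uses the state snapshot at the band midpoint age among
    alive persons; ``prevalence_crc`` covers preclinical plus diagnosed
    (alive) cancer and ``prevalence_any_advanced`` adds advanced
    adenomas.  Rates divide band event counts by band person-years.
    """
    bands = tuple(bands) if bands is not None else ((40, 50), (50, 60), (60, 70), (70, 80))
    quantities = tuple(quantities) if quantities is not None else DEFAULT_QUANTITIES
    out: dict[tuple, float] = {}
    for sex in sexes:
        cols = _sex_slice(sex)
        for lo, hi in bands:
            mid = (lo + hi) // 2
            counts = result.state_counts[mid - AGE_MIN][cols].sum(axis=0)
            alive = counts[: HealthState.DEATH_CRC].sum()
            if alive == 0:
                raise ValueError(
                    f"no alive individuals at band midpoint age {mid} for sex {sex!r}; "
                    "increase the cohort size"
                )
            sl = slice(lo - AGE_MIN, hi - AGE_MIN)
            py_inc = result.py_incidence[sl][:, cols].sum()
            py_mort = result.py_mortality[sl][:, cols].sum()
            cases = (result.inc_screen[sl][:, cols] + result.inc_symptom[sl][:, cols]).sum()
            deaths = result.crc_deaths[sl][:, cols].sum()
            values = {
                "prevalence_naa": counts[HealthState.NAA] / alive,
                "prevalence_aa": counts[HealthState.AA] / alive,
                "prevalence_crc": (
                    counts[HealthState.PRECLINICAL_CRC]
                    + counts[HealthState.CRC_SCREEN_DETECTED]
                    + counts[HealthState.CRC_SYMPTOM_DETECTED]
                )
                / alive,
                "prevalence_any_advanced": (
                    counts[HealthState.AA]
                    + counts[HealthState.PRECLINICAL_CRC]
                    + counts[HealthState.CRC_SCREEN_DETECTED]
                    + counts[HealthState.CRC_SYMPTOM_DETECTED]
                )
                / alive,
                "incidence": 1e5 * cases / py_inc if py_inc > 0 else float("nan"),
                "mortality": 1e5 * deaths / py_mort if py_mort > 0 else float("nan"),
            }
            for q in quantities:
                out[(q, sex, lo, hi)] = float(values[q])
    return out


def model_summaries(
    bundle: ParameterBundle,
    n: int,
    seed: int,
    bands: Sequence[tuple[int, int]] | None = None,
    quantities: Sequence[str] | None = None,
) -> dict[tuple, float]:
    """Run a no-screening cohort of size ``n`` and summarise it per band."""
    result = run_cohort(n=n, bundle=bundle, strategy=None, seed=seed)
    return summaries_from_result(result, bands=bands, quantities=quantities)


def calibration_objective(
    predicted: Mapping[tuple, float],
    targets: Sequence[CalibrationTarget],
    weights: Mapping[tuple, float] | None = None,
) -> float:
    """Weighted sum of squared standardised deviations.

    Each target contributes ``w * ((predicted - observed) / half_width)**2``,
    so a prediction sitting exactly on a CI bound contributes its weight.
    Zero iff every prediction equals its observed value.
    """
    total = 0.0
    for t in targets:
        if t.half_width <= 0:
            raise ValueError(f"target {t.key()}: zero CI half-width")
        try:
            pred = predicted[t.key()]
        except KeyError:
            raise KeyError(f"prediction missing for target {t.key()}") from None
        w = 1.0 if weights is None else float(weights.get(t.key(), 1.0))
        total += w * ((pred - t.value) / t.half_width) ** 2
    return float(total)


def ci_coverage_count(
    predicted: Mapping[tuple, float], targets: Sequence[CalibrationTarget]
) -> tuple[int, int]:
    """How many predictions fall inside their target's 95% CI."""
    covered = sum(
        1 for t in targets if t.ci_low <= predicted[t.key()] <= t.ci_high
    )
    return covered, len(targets)


# ---------------------------------------------------------------------------
# free-parameter mapping and the two-stage search
# ---------------------------------------------------------------------------


def apply_free_parameters(
    bundle: ParameterBundle, values: Mapping[str, float]
) -> ParameterBundle:
    """Return a bundle with named free parameters applied.

    Two naming schemes are understood:

    * ``"mult:<transition>"`` — multiply that transition probability in
      every band and both sexes (e.g. ``"mult:p_naa_to_aa"``);
    * ``"trans:<sex>:<age_lo>:<transition>"`` — set the probability of
      one (sex, band) cell directly.
    """
    probs = {sex: bundle.transitions.probs[sex].copy() for sex in SEXES}
    bands = bundle.transitions.bands
    for name, value in values.items():
        parts = name.split(":")
        if parts[0] == "mult" and len(parts) == 2:
            j = TRANSITION_FIELDS.index(parts[1])
            for sex in SEXES:
                probs[sex][:, j] = np.clip(probs[sex][:, j] * value, 0.0, 1.0)
        elif parts[0] == "trans" and len(parts) == 4:
            sex, lo, fieldname = parts[1], int(parts[2]), parts[3]
            i = [b[0] for b in bands].index(lo)
            j = TRANSITION_FIELDS.index(fieldname)
            probs[sex][i, j] = value
        else:
            raise KeyError(f"unrecognised free-parameter name {name!r}")
    return bundle.with_transitions(TransitionTable(bands=bands, probs=probs))


@dataclass
class CalibrationDiagnostics:
    objective: float
    evaluations: int
    best_parameters: dict[str, float]
    coverage: tuple[int, int]
    history: list[tuple[dict[str, float], float]]
    warning: str | None = None


def calibrate(
    targets: Sequence[CalibrationTarget],
    bounds: Mapping[str, tuple[float, float]],
    budget: int,
    seed: int,
    base_bundle: ParameterBundle,
    n_sim: int = 20_000,
    refine_sweeps: int = 2,
    evaluator: Callable[[ParameterBundle], Mapping[tuple, float]] | None = None,
) -> tuple[ParameterBundle, CalibrationDiagnostics]:
    """Fit the named free parameters to the targets.

    Stage 1 draws ``budget`` Latin-hypercube candidates over ``bounds``;
    stage 2 refines the best candidate by coordinate-wise quadratic
    descent (three-point parabola per coordinate, sweep repeated with a
    shrinking step).  Every candidate is scored with the same simulation
    seed, making the search deterministic given ``seed``.
    """
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(lo > hi):
        raise ValueError("each bound must satisfy lo <= hi")
    band_keys = sorted({(t.age_lo, t.age_hi) for t in targets})
    quantity_keys = tuple(dict.fromkeys(t.quantity for t in targets))

    if evaluator is None:

        def evaluator(b: ParameterBundle) -> Mapping[tuple, float]:
            return model_summaries(
                b, n=n_sim, seed=seed, bands=band_keys, quantities=quantity_keys
            )

    history: list[tuple[dict[str, float], float]] = []

    def score(x: np.ndarray) -> float:
        values = dict(zip(names, (float(v) for v in x)))
        bundle = apply_free_parameters(base_bundle, values)
        obj = calibration_objective(evaluator(bundle), targets)
        history.append((values, obj))
        return obj

    # stage 1: Latin-hypercube screen
    if budget < 1:
        raise ValueError("budget must be >= 1")
    span = hi - lo
    if np.all(span == 0):
        best_x = lo.copy()
        best_obj = score(best_x)
    else:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        candidates = lo + sampler.random(budget) * span
        midpoint = (lo + hi) / 2.0
        scores = np.array([score(x) for x in candidates])
        best_i = int(np.argmin(scores))
        best_x, best_obj = candidates[best_i].copy(), float(scores[best_i])
        midpoint_obj = score(midpoint)
        if midpoint_obj <= best_obj:
            best_x, best_obj = midpoint, midpoint_obj

        # stage 2: coordinate-wise quadratic descent
        step = span / 8.0
        for sweep in range(refine_sweeps):
            for d in range(len(names)):
                if step[d] == 0:
                    continue
                x_lo = best_x.copy()
                x_hi = best_x.copy()
                x_lo[d] = max(lo[d], best_x[d] - step[d])
                x_hi[d] = min(hi[d], best_x[d] + step[d])
                f_lo, f_hi = score(x_lo), score(x_hi)
                trial_points = [(x_lo, f_lo), (x_hi, f_hi)]
                # parabola through the three points, vertex clipped to bounds
                xs = np.array([x_lo[d], best_x[d], x_hi[d]])
                fs = np.array([f_lo, best_obj, f_hi])
                denom = (xs[0] - xs[1]) * (xs[0] - xs[2]) * (xs[1] - xs[2])
                if abs(denom) > 1e-15:
                    a = (
                        xs[2] * (fs[1] - fs[0])
                        + xs[1] * (fs[0] - fs[2])
                        + xs[0] * (fs[2] - fs[1])
                    ) / denom
                    if a > 0:
                        b = (
                            xs[2] ** 2 * (fs[0] - fs[1])
                            + xs[1] ** 2 * (fs[2] - fs[0])
                            + xs[0] ** 2 * (fs[1] - fs[2])
                        ) / denom
                        vx = float(np.clip(-b / (2 * a), lo[d], hi[d]))
                        x_v = best_x.copy()
                        x_v[d] = vx
                        trial_points.append((x_v, score(x_v)))
                for x_t, f_t in trial_points:
                    if f_t < best_obj:
                        best_x, best_obj = x_t.copy(), float(f_t)
            step /= 2.0

    best_values = dict(zip(names, (float(v) for v in best_x)))
    best_bundle = apply_free_parameters(base_bundle, best_values)
    predicted = evaluator(best_bundle)
    coverage = ci_coverage_count(predicted, targets)
    warning = None
    if np.any(span > 0):
        midpoint_entry = next(
            (obj for vals, obj in history if np.allclose(list(vals.values()), (lo + hi) / 2)),
            None,
        )
        if midpoint_entry is not None and best_obj >= midpoint_entry:
            warning = "no candidate improved on the bounds midpoint"
    diag = CalibrationDiagnostics(
        objective=best_obj,
        evaluations=len(history),
        best_parameters=best_values,
        coverage=coverage,
        history=history,
        warning=warning,
    )
    return best_bundle, diag


# ---------------------------------------------------------------------------
# rate ratios and equivalence testing
# ---------------------------------------------------------------------------


def rate_ratio_ci(
    model_rate: float,
    observed_rate: float,
    model_events: float,
    observed_events: float,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Model/observed rate ratio with a log-scale CI.

    The log standard error uses the usual Poisson approximation
    ``sqrt(1/model_events + 1/observed_events)``.
    """
    if model_rate <= 0 or observed_rate <= 0:
        raise ValueError("rates must be positive")
    if model_events < 1 or observed_events < 1:
        raise ValueError("event counts must be >= 1 for a defined rate-ratio CI")
    rr = model_rate / observed_rate
    se = math.sqrt(1.0 / model_events + 1.0 / observed_events)
    z = stats.norm.ppf(1 - alpha / 2)
    return rr, rr * math.exp(-z * se), rr * math.exp(z * se)


def _dersimonian_laird(
    log_rr: np.ndarray, se: np.ndarray
) -> tuple[float, float, float]:
    """Random-effects pooled estimate, its SE, and tau^2."""
    w = 1.0 / se**2
    fixed = float(np.sum(w * log_rr) / np.sum(w))
    q = float(np.sum(w * (log_rr - fixed) ** 2))
    df = len(log_rr) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * log_rr) / np.sum(w_star))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_star)))
    return pooled, pooled_se, tau2


def tost_equivalence(
    rr_by_band: Sequence[tuple[float, float]],
    margin: float = 0.2,
    bounds: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> TOSTResult:
    """Two one-sided tests for equivalence of a pooled rate ratio to 1.

    ``rr_by_band`` holds per-band ``(log rate ratio, SE)`` pairs, pooled
    by DerSimonian-Laird random-effects meta-analysis (a single band
    falls back to its own fixed estimate, with a warning).  Equivalence
    bounds default to ``(ln(1 - margin), ln(1 + margin))``; pass
    ``bounds=(-log(1.2), log(1.2))`` for symmetric log-scale bounds.
    Equivalent iff both one-sided p-values are below ``alpha``.
    """
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must lie in (0, 1)")
    arr = np.asarray(rr_by_band, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("rr_by_band must be a non-empty sequence of (log RR, SE) pairs")
    warning = None
    if arr.shape[0] == 1:
        pooled, pooled_se, tau2 = float(arr[0, 0]), float(arr[0, 1]), 0.0
        warning = "single band: fixed-effect fallback, no heterogeneity estimate"
    else:
        pooled, pooled_se, tau2 = _dersimonian_laird(arr[:, 0], arr[:, 1])
    lo_bound, hi_bound = bounds if bounds is not None else (
        math.log(1.0 - margin),
        math.log(1.0 + margin),
    )
    # H0_lower: true log RR <= lo_bound; reject when the estimate is well above
    p_lower = float(stats.norm.cdf((lo_bound - pooled) / pooled_se))
    # H0_upper: true log RR >= hi_bound; reject when the estimate is well below
    p_upper = float(stats.norm.cdf((pooled - hi_bound) / pooled_se))
    z = stats.norm.ppf(1 - alpha / 2)
    return TOSTResult(
        rate_ratio=math.exp(pooled),
        ci_low=math.exp(pooled - z * pooled_se),
        ci_high=math.exp(pooled + z * pooled_se),
        p_lower=p_lower,
        p_upper=p_upper,
        margin=margin,
        equivalent=max(p_lower, p_upper) < alpha,
        tau2=tau2,
        warning=warning,
    )
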