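import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from crcsim.fixtures import default_parameter_set
from crcsim.params import (
    CRCSurvivalProfile,
    InitialPrevalence,
    LifeTable,
    ParameterBundle,
    TestProfile,
    TransitionTable,
)


@pytest.fixture(scope="session")
def default_bundle():
    return default_parameter_set(seed=0)


def make_uniform_bundle(
    p_trans=(0.05, 0.10, 0.15, 0.30),
    p_other=0.02,
    q=(0.20, 0.15, 0.10, 0.08, 0.05),
    initial=(0.70, 0.20, 0.08, 0.02),
    screen_multiplier=1.0,
    tests=None,
):
    """A bundle with age/sex-constant parameters: the survival adjustment
    is disabled (source == target) so the engine's annual cancer-death
    probabilities equal ``q`` exactly, making closed-form comparison easy.
    """
    ages = np.arange(40, 81)
    h = -np.log1p(-p_other)  # all-cause hazard whose non-CRC death prob is p_other
    life = LifeTable(
        ages=ages,
        p_all_cause={s: np.full(41, h) for s in ("male", "female")},
        p_crc={s: np.zeros(41) for s in ("male", "female")},
    )
    trans = TransitionTable(
        bands=((40, 80),),
        probs={s: np.array([p_trans], dtype=float) for s in ("male", "female")},
    )
    ip = {
        s: InitialPrevalence(s, *initial) for s in ("male", "female")
    }
    surv = CRCSurvivalProfile(
        q=tuple(q), s5_source=0.5, s5_target=0.5,
        screen_detected_hazard_multiplier=screen_multiplier,
    )
    if tests is None:
        tests = {
            "FIT": TestProfile("FIT", 0.05, 0.26, 0.76, 0.95),
            "SIGMOIDOSCOPY": TestProfile("SIGMOIDOSCOPY", 0.59, 0.59, 0.61, 0.92),
            "COLONOSCOPY": TestProfile("COLONOSCOPY", 0.95, 0.95, 0.95, 1.0),
        }
    return ParameterBundle(
        initial_prevalence=ip,
        transitions=trans,
        life_table=life,
        crc_survival=surv,
        tests=tests,
    ).validate()


@pytest.fixture
def uniform_bundle():
    return make_uniform_bundle()


class ScriptedRNG:
    """Fake generator returning a predetermined sequence of uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, n=None):
        if n is None:
            return self.values.pop(0)
        return np.array([self.values.pop(0) for _ in range(n)])
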