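import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

from octadkit import (
    CrossParams,
    DerivativeObs,
    ObservationRecord,
    example_rt,
    get_preset,
    nucleus,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20150420)


@pytest.fixture
def eb4():
    return get_preset("EB4")


@pytest.fixture
def ibj5():
    return get_preset("IBj5")


@pytest.fixture
def uk14():
    return get_preset("UK14-1")


@pytest.fixture
def b362i():
    return get_preset("B362i")


@pytest.fixture
def rt():
    return example_rt()


def cross_parents(spec, g1="T", g2="N"):
    """Opposite-mating-type parents of the given segmental genotypes."""
    return nucleus(spec, g1, "A"), nucleus(spec, g2, "a")


def forced(p_alt, species="crassa", **kw):
    """CrossParams with a forced segregation pattern and no crossovers."""
    kw.setdefault("c_donor", 0.0)
    kw.setdefault("c_recipient", 0.0)
    return CrossParams(p_alt=p_alt, species=species, **kw)


# ---------------------------------------------------------------------------
# Worked strain observations: the published per-derivative evidence for the
# classifier's reference cases (strains 1E1, 2E1, 3E1 and 3I1).
# ---------------------------------------------------------------------------

def worked_observations():
    full = frozenset({"A", "B", "C"})
    return {
        "1E1": ObservationRecord(
            "1E1", full, [DerivativeObs(False, "A", frozenset({"B", "C"}))] * 25
        ),
        "2E1": ObservationRecord(
            "2E1",
            full,
            [DerivativeObs(False, "a", frozenset())] * 5
            + [DerivativeObs(False, "A", full)] * 5,
        ),
        "3E1": ObservationRecord(
            "3E1", full, [DerivativeObs(False, "a", full)] * 6
        ),
        "3I1": ObservationRecord(
            "3I1",
            frozenset({"A", "B"}),
            [DerivativeObs(False, "a", frozenset({"A", "B"}))] * 2
            + [DerivativeObs(False, "A", frozenset())] * 5
            + [DerivativeObs(False, "A", frozenset({"A"}))] * 2,
        ),
    }
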