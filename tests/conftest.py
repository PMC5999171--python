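import numpy as np
import pytest

from lynchpred import (Cohort, IndexPatient, default_config_table1,
                       generate_cohort, load_default_coeffs)
from lynchpred.scoring import CoefficientSet, Recipe


def make_patient(**kw) -> IndexPatient:
    """A valid CRC proband; override any field via keywords."""
    base = dict(id="P1", sex="female", num_crc="1", age_first_crc=55.0,
                any_proximal_crc=False, mutation_status="none")
    base.update(kw)
    return IndexPatient(**base)


@pytest.fixture
def patient() -> IndexPatient:
    return make_patient()


@pytest.fixture(scope="session")
def premm5_coeffs() -> CoefficientSet:
    return load_default_coeffs("premm5")


@pytest.fixture(scope="session")
def mmrpredict_coeffs() -> CoefficientSet:
    return load_default_coeffs("mmrpredict")


@pytest.fixture(scope="session")
def toy_multinomial() -> CoefficientSet:
    """Small hand-checkable four-gene model over two covariates."""
    enc = {
        "young": Recipe(kind="age", fieldname="age_first_crc",
                        shift=50.0, scale=-10.0, default=0.0),
        "fdr_crc": Recipe(kind="count", fieldname="fdr_crc_n", cap=2),
    }
    return CoefficientSet(
        model_name="toy",
        outcomes=["MLH1", "MSH2", "MSH6", "PMS2"],
        intercepts={"MLH1": -2.0, "MSH2": -2.5, "MSH6": -1.5, "PMS2": -3.0},
        coefficients={
            "MLH1": {"young": 0.8, "fdr_crc": 0.5},
            "MSH2": {"young": 0.6},
            "MSH6": {"fdr_crc": 0.3},
            "PMS2": {},
        },
        encoding=enc,
    ).validate()


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    return generate_cohort(default_config_table1(n=400, seed=1234))


@pytest.fixture(scope="session")
def medium_cohort() -> Cohort:
    return generate_cohort(default_config_table1(n=3000, seed=97531))


def spawn_seeds(master: int, k: int) -> list[int]:
    """Independent sub-seeds below 2^31 from one master seed."""
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(master).spawn(k)]
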