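import dataclasses

import numpy as np
import pandas as pd
import pytest

from iolpower.cohort import COHORT_COLUMNS
from iolpower.optics import OpticsConstants
from iolpower.synthetic import SyntheticConfig, generate_cohort

#: the study population's average eye
AVG_K, AVG_AL = 43.3, 23.03


@pytest.fixture(scope="session")
def consts() -> OpticsConstants:
    return OpticsConstants()


def make_case(**overrides):
    """One filter-passing surgical case with average biometry."""
    case = {
        "eye_id": "E00000", "patient_id": "P00000", "eye": "right",
        "age_years": 57.0, "k_d": AVG_K, "acd_mm": 3.10, "al_mm": AVG_AL,
        "rx_pre_d": 1.85, "iol_implanted_d": 23.0, "rx_post_d": 0.25,
        "udva_pre": 0.5, "cdva_pre": 0.3, "udva_post": 0.1, "cdva_post": 0.0,
        "astig_pre_d": 1.0, "days_postop": 30.0,
        "surgery_text": "", "finding_text": "", "diagnosis_text": "",
    }
    case.update(overrides)
    return case


def make_cohort(cases):
    rows = []
    for i, c in enumerate(cases):
        c = dict(c)
        c.setdefault("eye_id", f"E{i:05d}")
        c.setdefault("patient_id", f"P{i:05d}")
        rows.append(make_case(**c))
    return pd.DataFrame(rows)[COHORT_COLUMNS]


@pytest.fixture(scope="session")
def small_cohort():
    """600-eye synthetic cohort with default study conditions."""
    cohort, truth = generate_cohort(SyntheticConfig(n_eyes=600, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def noise_free_config() -> SyntheticConfig:
    """Deterministic forward model: no ELP deviation, noise or quantization."""
    return SyntheticConfig(
        n_eyes=400, seed=7, sigma_elp_mm=0.0, sigma_meas_d=0.0,
        rx_quantum_d=0.0, a_constant_surgeon=119.1,
    )
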