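import numpy as np
import pandas as pd
import pytest

from readerstudy import SimulationConfig, Study, simulate_study


def make_study(reading_rows, case_rows, reader_rows) -> Study:
    """Assemble a Study from plain row dicts (test helper)."""
    return Study(
        readings=pd.DataFrame(reading_rows),
        cases=pd.DataFrame(case_rows),
        readers=pd.DataFrame(reader_rows),
    )


def reading(reader, case, modality, category, suspicion, lesions=None):
    if lesions is None:
        lesions = str(category) if category >= 3 else ""
    return {"reader_id": reader, "case_id": case, "modality": modality,
            "patient_pirads": category, "suspicion": suspicion, "lesions": lesions}


def case(case_id, label, block="B1", center="X", gg=None, psad=0.12):
    gg = (2 if label else 0) if gg is None else gg
    return {"case_id": case_id, "center": center, "block_id": block,
            "label": label, "gg": gg, "psad": psad, "psa": 7.0, "volume": 50.0,
            "age": 66.0}


def reader(reader_id, block="B1", expertise="expert"):
    return {"reader_id": reader_id, "block_id": block, "expertise": expertise}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # 16 readers x 40 cases in 4 blocks: 2 experts + 2 nonexperts and
    # 10 cases (3-4 positives) per block
    return SimulationConfig(n_readers=16, n_cases=40, expert_fraction=0.5)


@pytest.fixture(scope="session")
def small_study(small_config) -> Study:
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def default_study() -> Study:
    """One full-size synthetic study (62 readers, 400 cases)."""
    return simulate_study(SimulationConfig(), seed=5)


@pytest.fixture
def two_reader_study() -> Study:
    """Hand-size paired study: 1 block, 2 readers, 4 cases (2 diseased)."""
    cases = [case("C1", 1), case("C2", 0), case("C3", 1), case("C4", 0)]
    readers = [reader("R1"), reader("R2")]
    rows = []
    scores = {
        ("R1", "bp"): {"C1": 80, "C2": 20, "C3": 60, "C4": 40},
        ("R1", "mp"): {"C1": 85, "C2": 15, "C3": 70, "C4": 30},
        ("R2", "bp"): {"C1": 70, "C2": 30, "C3": 40, "C4": 50},
        ("R2", "mp"): {"C1": 75, "C2": 25, "C3": 55, "C4": 45},
    }
    cats = {"C1": 5, "C2": 2, "C3": 3, "C4": 4}
    for (r, m), sc in scores.items():
        for c, s in sc.items():
            rows.append(reading(r, c, m, cats[c], s))
    return make_study(rows, cases, readers)
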