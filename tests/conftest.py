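import numpy as np
import pytest

from ppasym.grid import LAYERS, Cohort, EyeRecord, ThicknessGrid
from ppasym.simulate import CohortConfig, generate_cohort


def make_grid(subject_id="S1", layer="RNFL", laterality="R", fill=50.0, values=None):
    """Build a ThicknessGrid from a constant or an explicit 8x8 array."""
    if values is None:
        values = np.full((8, 8), float(fill))
    return ThicknessGrid(subject_id, layer, laterality, np.asarray(values, dtype=float))


def make_eye(subject_id="S1", laterality="R", layers=("RNFL",), fill=50.0, values=None):
    eye = EyeRecord(subject_id, laterality)
    for layer in layers:
        eye.add_grid(make_grid(subject_id, layer, laterality, fill=fill, values=values))
    return eye


@pytest.fixture
def constant_grid():
    return make_grid(fill=50.0)


@pytest.fixture
def symmetric_cohort():
    """Five eyes, all layers, every grid constant -> zero asymmetry everywhere."""
    eyes = [make_eye(f"S{i}", "R" if i % 2 else "L", layers=LAYERS, fill=50.0 + i) for i in range(5)]
    return Cohort(eyes=eyes, provenance="symmetric toy cohort")


@pytest.fixture(scope="session")
def reference_cohort():
    """Default-calibration 300-eye cohort shared across tests (fixed seed)."""
    return generate_cohort(CohortConfig(seed=7))
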