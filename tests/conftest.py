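import numpy as np
import pandas as pd
import pytest

from nutriage.panel import default_panel
from nutriage.simulate import SimulationConfig, generate_cohort, simulate


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """150 subjects x up to 4 visits with biomarkers; shared across tests."""
    cfg = SimulationConfig(n_subjects=150, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def demo_cohort():
    """Demographics + intakes only (no biomarkers)."""
    cfg = SimulationConfig(n_subjects=200, seed=5)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_filter_table(rows):
    """Helper: build a minimal table for the exclusive-dataset filters.

    ``rows`` is a list of dicts with subject_id, weight_kg, height_m and
    optional flags.
    """
    defaults = {"diabetes": False, "prescribed_diet": False, "visit": 1}
    recs = []
    for r in rows:
        rec = {**defaults, **r}
        rec.setdefault("bmi", rec["weight_kg"] / rec["height_m"] ** 2)
        recs.append(rec)
    return pd.DataFrame(recs)
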