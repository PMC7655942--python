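import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lipidscan.pipeline import prepare_cohort
from lipidscan.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one planted prevalent and one incident effect."""
    cfg = SimulationConfig(
        n_participants=600,
        n_classes=4,
        species_per_class=10,
        seed=42,
        planted_prevalent={"PC(30:0)": 0.6},
        planted_incident={"PE(30:0)": 0.5},
    )
    conc, meta, truth = generate_cohort(cfg)
    return cfg, conc, meta, truth


@pytest.fixture(scope="session")
def prepared(small_cohort):
    cfg, conc, meta, truth = small_cohort
    return prepare_cohort(conc, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_metadata(rows: list[dict]) -> pd.DataFrame:
    """Build a metadata frame from terse row dicts with sensible defaults."""
    defaults = dict(
        cohort_id="TOY",
        timepoint=0,
        age=75.0,
        sex="F",
        bmi=26.0,
        total_cholesterol=5.0,
        hdl_c=1.5,
        triglycerides=1.2,
        apoe4_count=0,
        statin=False,
        omega3=False,
        site=None,
        fasting=None,
        diagnosis="CN",
        followup_years=5.0,
        converted=False,
    )
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        rec.setdefault("participant_id", f"P{i}")
        rec.setdefault("sample_id", f"S{i}")
        out.append(rec)
    return pd.DataFrame(out).set_index("sample_id")
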