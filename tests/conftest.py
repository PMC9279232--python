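import numpy as np
import pandas as pd
import pytest

from msstratify import BiomarkerTable, EventGrid, SimulationConfig


@pytest.fixture
def toy_grid():
    """Two biomarkers, one level each: the smallest nontrivial grid."""
    return EventGrid(("A", "B"), ((1.0,), (1.0,)), (5.0, 5.0))


@pytest.fixture
def three_event_grid():
    """One two-level biomarker plus one single-level biomarker."""
    return EventGrid(("A", "B"), ((1.0, 2.0), (1.0,)), (5.0, 5.0))


@pytest.fixture
def small_config():
    """A reduced study: 4 gray-matter regions + lesion volume, 2 z-levels."""
    return SimulationConfig(
        n_patients=120,
        n_hc=60,
        n_external=40,
        gm_biomarkers=("thalamus_left", "thalamus_right", "insula_left", "cuneus_left"),
        dgm_biomarkers=("thalamus_left", "thalamus_right"),
        levels=(1.0, 2.0),
        sigma_gen=0.25,
    )


@pytest.fixture
def tiny_visits():
    """Three subjects with 1-3 visits each; two biomarkers."""
    rows = []
    for sid, times in {"S1": [0.0, 1.1, 2.3], "S2": [0.0, 0.9], "S3": [0.0]}.items():
        for v, t in enumerate(times):
            rows.append(
                {
                    "subject_id": sid,
                    "visit_index": v,
                    "years_from_baseline": t,
                    "age_years": 40.0 + t,
                    "sex": "F" if sid != "S2" else "M",
                    "gm": 5.0 - 0.1 * v,
                    "tlv": 2.0 + 0.5 * v,
                }
            )
    return BiomarkerTable(pd.DataFrame(rows), scale="raw")
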