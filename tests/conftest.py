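import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nullmark.cohort_io import Cohort, PopulationRecord, ReferencePanel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Joint phenotype counts of the study cohort (n=300):
# (GSTM1, GSTT1) = (+,+) 104, (+,null) 80, (null,+) 98, (null,null) 18.
STUDY_JOINT_COUNTS = {
    (False, False): 104,
    (False, True): 80,
    (True, False): 98,
    (True, True): 18,
}


def make_cohort(joint_counts=None, loci=("GSTM1", "GSTT1")) -> Cohort:
    joint_counts = joint_counts or STUDY_JOINT_COUNTS
    rows = []
    for combo, count in joint_counts.items():
        rows.extend([combo] * count)
    n = len(rows)
    calls = pd.DataFrame(
        rows,
        columns=list(loci),
        index=pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id"),
        dtype=bool,
    )
    return Cohort(calls)


@pytest.fixture
def study_cohort() -> Cohort:
    """Cohort reproducing the study's joint phenotype counts."""
    return make_cohort()


@pytest.fixture
def tiny_panel() -> ReferencePanel:
    """Small panel with a missing locus and a missing sample size."""
    return ReferencePanel(
        [
            PopulationRecord("Alpha", 120, {"GSTM1": 0.510, "GSTT1": 0.110}),
            PopulationRecord("Beta", 40, {"GSTM1": 0.400, "GSTT1": 0.000}),
            PopulationRecord("NoLocus", 173, {"GSTT1": 0.179}),
            PopulationRecord("NoSize", None, {"GSTM1": 0.507, "GSTT1": 0.107}),
        ],
        provenance="test fixture",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
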