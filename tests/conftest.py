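import numpy as np
import pandas as pd
import pytest

from stressrec.matrices import OmicsMatrix
from stressrec.synthetic import (
    DependencyCohortConfig,
    SyntheticStudyConfig,
    simulate_dependency_cohort,
    simulate_timecourse_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact default-condition study reused across read-only tests."""
    cfg = SyntheticStudyConfig(
        n_transcripts=200, n_proteins=200, n_metabolites=40, seed=11
    )
    return simulate_timecourse_study(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = DependencyCohortConfig(n_lines=120, n_genes=1500, n_tumors=80, seed=7)
    return simulate_dependency_cohort(cfg)


def toy_matrix(values, days, omic="transcript", log_scale=False):
    """Build an OmicsMatrix from a plain array with one replicate tag per column."""
    values = np.asarray(values, dtype=float)
    reps = {}
    sample_ids, meta = [], []
    for d in days:
        reps[d] = reps.get(d, 0) + 1
        sid = f"d{d}_r{reps[d]}"
        sample_ids.append(sid)
        meta.append((sid, d, reps[d], "treated"))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "day", "replicate", "arm"]
    ).set_index("sample_id")
    vals = pd.DataFrame(
        values, index=[f"F{i}" for i in range(values.shape[0])], columns=sample_ids
    )
    return OmicsMatrix(values=vals, samples=samples, omic=omic, log_scale=log_scale)
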