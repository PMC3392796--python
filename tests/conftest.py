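import numpy as np
import pandas as pd
import pytest

import lscpanel as lp


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale study design: full cohort structure, few phantoms."""
    return lp.default_design(seed=11, phantoms_per_section=400)


@pytest.fixture(scope="session")
def small_study(small_design):
    tables, metadata = lp.generate_study(small_design)
    return tables, metadata


@pytest.fixture(scope="session")
def small_summaries(small_study):
    tables, metadata = small_study
    return lp.summarize_study(tables), metadata


def make_dataset(rng, n_control=14, n_case=17, markers=("M1", "M2"), shift=0.0):
    """A CohortDataset built directly from Gaussian values (no generator)."""
    patients = [f"c{i}" for i in range(n_control)] + [f"r{i}" for i in range(n_case)]
    labels = pd.Series(
        ["control"] * n_control + ["RA(+)"] * n_case, index=patients, name="cohort"
    )
    values = pd.DataFrame(
        rng.normal(0.0, 1.0, (len(patients), len(markers))),
        index=patients,
        columns=list(markers),
    )
    values.iloc[n_control:, :] += shift
    return lp.CohortDataset(parameter="mfi_corrected", values=values, labels=labels)
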