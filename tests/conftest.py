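import numpy as np
import pandas as pd
import pytest

from dmharmonize import (
    ConnectivityTable,
    SubjectMetadata,
    default_study_specs,
    generate_paired_sites,
)


@pytest.fixture
def small_table():
    """A tiny 4-region, 3-subject table with known values."""
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 1.0, size=(3, 6))
    values[0, 0] = 0.0
    return ConnectivityTable(
        values=values, subject_ids=["s1", "s2", "s3"], n_regions=4
    )


@pytest.fixture
def small_meta():
    return SubjectMetadata(
        pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3"],
                "site": ["A", "A", "B"],
                "sex": ["M", "F", "M"],
                "age": [70.0, 65.0, np.nan],
            }
        )
    )


@pytest.fixture(scope="session")
def paired_study():
    """The default two-site synthetic study plus merged metadata."""
    spec_ref, spec_new = default_study_specs(seed=7)
    (ref, meta_ref), (new, meta_new) = generate_paired_sites(spec_ref, spec_new)
    merged = SubjectMetadata(
        pd.concat([meta_ref.frame, meta_new.frame]).reset_index()
    )
    return ref, new, merged
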