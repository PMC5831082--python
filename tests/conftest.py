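"""Shared fixtures: small synthetic designs and communities.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from microdyn.io_profiles import AbundanceTable, SampleMetadata
from microdyn.synth import SimulationSpec, simulate_abundance_table, simulate_design


@pytest.fixture(scope="session")
def hmp_like_spec() -> SimulationSpec:
    """The reference study conditions: 90 subjects, <=3 visits, 1-12 month
    gaps, 15% technical replicates, 5% technical noise evenly-split truth."""
    return SimulationSpec(seed=2)


@pytest.fixture(scope="session")
def hmp_design(hmp_like_spec):
    design, meta = simulate_design(hmp_like_spec)
    return design


@pytest.fixture(scope="session")
def hmp_meta(hmp_like_spec):
    _, meta = simulate_design(hmp_like_spec)
    return meta


@pytest.fixture(scope="session")
def community():
    """Multi-site community tables with planted truth (session-cached)."""
    return simulate_abundance_table(SimulationSpec(seed=11))


@pytest.fixture()
def tiny_table() -> AbundanceTable:
    frame = pd.DataFrame(
        {
            "s1": [0.5, 0.3, 0.2],
            "s2": [0.1, 0.6, 0.3],
            "s3": [0.25, 0.25, 0.5],
        },
        index=["fA", "fB", "fC"],
    )
    return AbundanceTable(frame)


@pytest.fixture()
def tiny_meta() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "subject_id": ["p1", "p1", "p2"],
                "body_site": ["stool", "stool", "stool"],
                "collection_day": [0, 100, 0],
                "replicate_group": ["g1", "g2", "g3"],
                "visit_number": [1, 2, 1],
            }
        )
    )


def random_abundance_table(rng: np.random.Generator, n_features=8, n_samples=12):
    vals = rng.random((n_features, n_samples))
    vals /= vals.sum(axis=0)
    return AbundanceTable(
        pd.DataFrame(
            vals,
            index=[f"f{i}" for i in range(n_features)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
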