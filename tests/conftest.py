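"""Shared fixtures: small synthetic studies and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from myolab.containers import ExpressionMatrix
from myolab.simulate import (
    MixtureParams,
    StudyDesign,
    default_catalog,
    generate_study,
)


@pytest.fixture(scope="session")
def default_study():
    """Default-parameter study: composition shift + transcriptional effects."""
    return generate_study(default_catalog(seed=11), MixtureParams(), StudyDesign(seed=11))


@pytest.fixture(scope="session")
def dilution_study():
    """Composition shift only: every beta = 1, f means 0.05 vs 0.30."""
    catalog = default_catalog(
        class_sizes={"labour_induced": 0, "labour_repressed": 0}, seed=7
    )
    return generate_study(catalog, MixtureParams(), StudyDesign(seed=7))


@pytest.fixture(scope="session")
def null_study():
    """Global null: no transcriptional effects, equal mixture distributions."""
    catalog = default_catalog(
        class_sizes={
            "muscle_specific": 0,
            "leukocyte_specific": 0,
            "labour_induced": 0,
            "labour_repressed": 0,
            "housekeeping": 1000,
            "negative_control": 100,
        },
        seed=5,
    )
    mix = MixtureParams(f_labour=(2.0, 38.0), f_nonlabour=(2.0, 38.0))
    return generate_study(catalog, mix, StudyDesign(n_labour=8, n_nonlabour=8, seed=5))


def make_matrix(values: np.ndarray, n_controls: int = 0, prefix: str = "p") -> ExpressionMatrix:
    """Wrap a plain array as an ExpressionMatrix; the last ``n_controls``
    rows are flagged as negative controls."""
    n_probes, n_samples = values.shape
    probes = [f"{prefix}{i}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    flags = pd.Series([i >= n_probes - n_controls for i in range(n_probes)], index=probes)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        is_control=flags,
    )


def two_group_metadata(n_labour: int, n_nonlabour: int, sample_ids=None) -> pd.DataFrame:
    ids = sample_ids or [f"s{j}" for j in range(n_labour + n_nonlabour)]
    return pd.DataFrame(
        {"group": ["labour"] * n_labour + ["nonlabour"] * n_nonlabour},
        index=pd.Index(ids, name="sample_id"),
    )
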