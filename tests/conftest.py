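"""Shared fixtures: tiny deterministic cohorts and matrix builders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bloodshift as bs

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(values, groups, unit="FPKM", months=None, transcript_ids=None):
    """Build an ExpressionMatrix from an array and per-sample group labels."""
    values = np.asarray(values, dtype=float)
    n_t, n_s = values.shape
    sample_ids = [f"S{i:02d}" for i in range(n_s)]
    samples = pd.DataFrame({"group": list(groups)}, index=pd.Index(sample_ids, name="sample_id"))
    if months is not None:
        samples["months_since_event"] = months
    if transcript_ids is None:
        transcript_ids = [f"T{i:03d}" for i in range(n_t)]
    df = pd.DataFrame(values, index=pd.Index(transcript_ids, name="transcript_id"), columns=sample_ids)
    return bs.ExpressionMatrix(df, samples, unit=unit)


@pytest.fixture(scope="session")
def small_scenario():
    """A 600-transcript default scenario (session-scoped: read-only)."""
    return bs.default_acute_scenario(11, n_transcripts=600)


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    sc = small_scenario
    return bs.generate_cohort(sc.annotation, sc.signatures, sc.design)


@pytest.fixture(scope="session")
def small_fpkm(small_scenario, small_cohort):
    exonic, _, _, _ = small_cohort
    return bs.compute_fpkm(exonic, small_scenario.annotation)
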