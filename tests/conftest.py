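"""Shared fixtures: small deterministic synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import hdxpipe as hp
from hdxpipe.core import MaxLabelControl


@pytest.fixture(scope="session")
def toy_protein() -> hp.ProteinContext:
    return hp.ProteinContext("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ", name="toy")


@pytest.fixture(scope="session")
def study_truth() -> hp.StudyTruth:
    """Default two-state study with one destabilized region and the EX1 segment."""
    return hp.default_study_truth(
        seed=7, designed_regions=(hp.DesignedRegion(200, 230, 1.5),), include_ex1=True
    )


@pytest.fixture(scope="session")
def study_data(study_truth) -> "hp.simulate.StudyData":
    return hp.generate_study(study_truth)


@pytest.fixture(scope="session")
def study_series(study_data):
    peptides = study_data.peptide_records()
    controls = {
        (int(r.start), int(r.end), str(r.sequence)): MaxLabelControl(
            peptide=peptides[(int(r.start), int(r.end), str(r.sequence))],
            m_max=float(r.m_max),
        )
        for r in study_data.max_label.itertuples(index=False)
    }
    return hp.summarize_uptake(study_data.measurements, peptides, controls)


@pytest.fixture(scope="session")
def study_comparison(study_data, study_series):
    return hp.compare_states(study_data.measurements, study_series, "Na", "K")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
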