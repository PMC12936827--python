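"""Shared fixtures: tiny hand-built matrices and a default synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from npxscreen import (
    AnalysisConfig,
    Arm,
    NPXMatrix,
    ProteinAssay,
    SampleRecord,
    Sex,
    SimulationConfig,
    Timepoint,
    simulate_full,
    validate_design,
)


def make_matrix(values, protein_ids, samples, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return NPXMatrix(
        values=values,
        missing_mask=np.asarray(mask, dtype=bool),
        proteins=[ProteinAssay(assay_id=g) for g in protein_ids],
        samples=samples,
    )


def make_sample(sample_id, subject_id, arm, timepoint, **kw):
    return SampleRecord(
        sample_id=sample_id,
        subject_id=subject_id,
        arm=Arm(arm),
        timepoint=Timepoint(timepoint),
        sex=Sex(kw.pop("sex", "unknown")),
        **kw,
    )


def make_trial_samples(n_treatment, n_control, skip=()):
    """Complete two-timepoint samples for both arms, minus any (subject, tp) in skip."""
    samples = []
    for arm, prefix, n in (("treatment", "T", n_treatment), ("control", "C", n_control)):
        for i in range(n):
            subj = f"{prefix}{i + 1:02d}"
            for tp, suffix in (("baseline", "B"), ("post", "P")):
                if (subj, tp) in skip:
                    continue
                samples.append(make_sample(f"{subj}_{suffix}", subj, arm, tp))
    return samples


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort with scores and truth."""
    matrix, truth = simulate_full(SimulationConfig(seed=11))
    return matrix, truth


@pytest.fixture(scope="session")
def default_design(default_cohort):
    matrix, _ = default_cohort
    return validate_design(matrix)


@pytest.fixture()
def analysis_config():
    return AnalysisConfig()
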