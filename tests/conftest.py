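"""Shared fixtures: tiny hand-built datasets and simulated cohorts."""

import numpy as np
import pytest

from fupk import (AnalysisDataset, CohortSpec, ConcentrationObservation,
                  DoseEvent, SubjectRecord, final_model, generate_cohort,
                  simulate_concentrations)


def make_subject(sid, **kw):
    defaults = dict(sex="male", age=60.0, height=1.75, bsa=1.97,
                    smi_psoas=1.48, smi_back=3.78, smi_total_hu=9.58,
                    smi_total_seg=50.26, ct_offset_days=0.0)
    defaults.update(kw)
    return SubjectRecord(subject_id=sid, **defaults)


@pytest.fixture
def toy_dataset():
    """Two subjects, one 24-h infusion and two steady-state samples each."""
    subjects = [make_subject("A", bsa=1.8), make_subject("B", bsa=2.2)]
    doses = [DoseEvent("A", 1, 4000.0, 24.0), DoseEvent("B", 1, 5000.0, 24.0)]
    obs = [
        ConcentrationObservation("A", 1, 18.0, 820.0),
        ConcentrationObservation("A", 1, 22.0, 910.0),
        ConcentrationObservation("B", 1, 18.0, 750.0),
        ConcentrationObservation("B", 1, 22.0, 801.0),
    ]
    return AnalysisDataset(subjects=subjects, doses=doses, observations=obs)


@pytest.fixture(scope="session")
def small_simulated():
    """Five subjects simulated under the published final model."""
    model = final_model()
    rng = np.random.default_rng(7)
    ds = generate_cohort(CohortSpec(n_subjects=5), seed=rng)
    return simulate_concentrations(ds, model, seed=rng), model


@pytest.fixture(scope="session")
def study_scale_simulated():
    """One study-scale cohort (111 subjects) under the final model."""
    model = final_model()
    rng = np.random.default_rng(11)
    ds = generate_cohort(seed=rng)
    return simulate_concentrations(ds, model, seed=rng), model
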