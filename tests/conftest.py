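import numpy as np
import pytest

from immunoprofiles.core import (
    ClinicalAnnotations,
    CohortTable,
    MarkerDescriptor,
    build_registry,
)


def make_table(values, marker_ids=None, measures=None, patient_ids=None, mask=None):
    """Small helper to build ad-hoc cohorts in tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    marker_ids = marker_ids or [f"m{j}" for j in range(p)]
    measures = measures or ["concentration"] * p
    units = {"percent": "%", "count": "cells/µL", "concentration": "pg/mL"}
    markers = [
        MarkerDescriptor(mid, "global", mid, meas, units[meas])
        for mid, meas in zip(marker_ids, measures)
    ]
    patient_ids = patient_ids or [f"P{i}" for i in range(n)]
    mask = np.zeros((n, p), dtype=bool) if mask is None else np.asarray(mask, bool)
    return CohortTable(patient_ids, markers, values, mask)


def make_annotations(classes, patient_ids=None, fazekas_pv=None, fazekas_deep=None):
    n = len(classes)
    patient_ids = patient_ids or [f"P{i}" for i in range(n)]
    return ClinicalAnnotations(
        patient_ids,
        np.asarray(classes, dtype=object),
        np.full(n, np.nan) if fazekas_pv is None else np.asarray(fazekas_pv, float),
        np.full(n, np.nan) if fazekas_deep is None else np.asarray(fazekas_deep, float),
    )


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def substudy():
    from immunoprofiles.synth import generate_nci_substudy

    return generate_nci_substudy(7)


@pytest.fixture(scope="session")
def profile_cohort():
    from immunoprofiles.synth import GeneratorConfig, generate_profile_cohort

    return generate_profile_cohort(GeneratorConfig(seed=1))
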