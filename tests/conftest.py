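"""Shared fixtures: small synthetic populations and configs.

Everything is generated in-process from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from prodrome.phenotyping import PhenotypeConfig, assemble_cohort
from prodrome.records import ClinicalEvent, PatientRecord
from prodrome.synthetic_ehr import (
    SimulationConfig,
    TreatmentSimConfig,
    simulate_ghri_population,
    simulate_pamf_population,
)


@pytest.fixture(scope="session")
def pheno_config() -> PhenotypeConfig:
    return PhenotypeConfig()


@pytest.fixture(scope="session")
def small_pamf():
    """700 patients, 100 cases — the smallest population exercising the
    full phenotyping + matching path."""
    return simulate_pamf_population(
        SimulationConfig(n_patients=700, prevalence=1 / 7, seed=1)
    )


@pytest.fixture(scope="session")
def small_cohort(small_pamf, pheno_config):
    return assemble_cohort(
        small_pamf.events, small_pamf.patients, pheno_config, seed=1
    )


@pytest.fixture(scope="session")
def small_ghri():
    return simulate_ghri_population(TreatmentSimConfig(n_patients=800, seed=2))


def make_record(
    patient_id: str = "p1",
    events: list[tuple] | None = None,
    birth_year: int = 1970,
    gender: str = "F",
) -> PatientRecord:
    """Terse record builder: events are (date, type, code[, negated, fh])
    tuples; a (date, 'phq9', score) triple becomes a scored event."""
    built = []
    for ev in events or []:
        date, etype, code = ev[0], ev[1], ev[2]
        negated = ev[3] if len(ev) > 3 else False
        fh = ev[4] if len(ev) > 4 else False
        if etype == "phq9":
            built.append(
                ClinicalEvent(patient_id, date, etype, "", value=float(code))
            )
        else:
            built.append(
                ClinicalEvent(patient_id, date, etype, str(code), negated, fh)
            )
    return PatientRecord.from_events(patient_id, built, birth_year, gender)
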