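"""Shared fixtures: reference parameters and small simulated datasets."""

import math

import numpy as np
import pytest
from hypothesis import settings

from propofol_pkpd import (
    BiophaseParameters,
    DoseEvent,
    Observation,
    PDParameters,
    PKParameters,
    StudyDataset,
    Subject,
    generate_trial,
    pk_model_spec,
    solve_pk,
)
from propofol_pkpd.nlme import PopulationModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: Final population PK estimates used as simulation truth throughout.
FINAL_PK = PKParameters(CL=1.37, Q=1.15, V1=3.6, V2=76.8)
#: BIS biophase (two effect compartments) and sigmoid Emax truth.
BIS_BIOPHASE = BiophaseParameters(ke0=0.102, ke12=0.121, ke21=0.172, order=2)
BIS_PD = PDParameters(E0=100.0, Emax=100.0, EC50=3.51, gamma=1.43)
#: cAAI biophase (single effect compartment) and Emax truth.
CAAI_BIOPHASE = BiophaseParameters(ke0=0.067, order=1)
CAAI_PD = PDParameters(E0=63.4, Emax=0.786 * 63.4, EC50=2.14, gamma=6.85)


def make_toy_pk_dataset(
    n_subjects: int = 3,
    seed: int = 1,
    omega2_cl: float = 0.05,
    sigma: float = 0.15,
    times=(5.0, 30.0, 90.0, 240.0),
    truth: PKParameters = FINAL_PK,
) -> StudyDataset:
    """Tiny PK dataset: bolus + 2 h infusion, a few samples per subject."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        doses = [
            DoseEvent(start=0.0, amount=200.0, duration=10.0 / 60.0),
            DoseEvent(start=10.0 / 60.0, amount=360.0, duration=120.0),
        ]
        eta = rng.normal(0.0, math.sqrt(omega2_cl))
        pk_i = truth.replace(CL=truth.CL * math.exp(eta))
        cb = solve_pk(pk_i, doses, list(times)).cb
        obs = [
            Observation(time=t, value=float(math.exp(math.log(c) + rng.normal(0.0, sigma))),
                        obs_type="conc")
            for t, c in zip(times, cb)
        ]
        subjects.append(
            Subject(id=f"T{i}", weight=50.0 + 5 * i, age=14.0 + i, sex="F",
                    remi_rate=0.5, doses=doses, observations=obs)
        )
    return StudyDataset(subjects)


@pytest.fixture(scope="session")
def study_trial() -> StudyDataset:
    """One default synthetic trial (14 subjects, full design)."""
    return generate_trial(seed=20250901)


@pytest.fixture(scope="session")
def study_pk_fit(study_trial):
    """Population PK fit of the session trial (shared to save refits)."""
    model = PopulationModel(study_trial, pk_model_spec())
    return model.fit(compute_se=False)


@pytest.fixture(scope="session")
def toy_pk_dataset() -> StudyDataset:
    return make_toy_pk_dataset(n_subjects=3, seed=1)
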