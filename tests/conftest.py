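"""Shared fixtures: one synthetic study reused across the suite.

The expensive artifacts (trained brain-age model, GP normative set) are
session-scoped; everything downstream reuses them so the suite stays
within a few minutes.
"""

import numpy as np
import pytest

from padkit.bias import PadBiasCorrector, compute_pad
from padkit.brain_age import BrainAgeModel
from padkit.normative import NormativeModelSet
from padkit.simulate import (
    ClinicalCohortConfig,
    default_clinical_coupling,
    default_trajectory_config,
    generate_clinical_cohort,
    generate_normative_population,
)

# small cascade settings for tests that only exercise mechanics, not accuracy
FAST_NET = dict(n_layers=3, width=6, max_iter=80)


@pytest.fixture(scope="session")
def traj():
    return default_trajectory_config()


@pytest.fixture(scope="session")
def train_cohort(traj):
    """Normative training population (n=500, ages 14-92)."""
    return generate_normative_population(500, traj, seed=101)


@pytest.fixture(scope="session")
def gm_model(train_cohort):
    """GM brain-age model trained on the session training population."""
    return BrainAgeModel(modality="GM", random_state=7).fit(
        train_cohort.tables["GM"], train_cohort.ages, train_cohort.sex_codes
    )


@pytest.fixture(scope="session")
def hc_cohort(traj):
    """Healthy-control-like application group (n=200, zero offset)."""
    return generate_clinical_cohort(
        ClinicalCohortConfig("HC", 200, pad_shift=0.0), traj, seed=102
    )


@pytest.fixture(scope="session")
def msa_cohort(traj):
    """MSA-like group with a +9-year brain-age offset and coupled scores."""
    return generate_clinical_cohort(
        ClinicalCohortConfig(
            "MSA", 200, pad_shift=9.0,
            clinical_coupling=default_clinical_coupling(),
        ),
        traj,
        seed=103,
    )


@pytest.fixture(scope="session")
def hc_corrector(gm_model, hc_cohort):
    """Bias correction fitted on the HC group's GM PAD."""
    pad = compute_pad(
        gm_model.predict(hc_cohort.tables["GM"], hc_cohort.sex_codes), hc_cohort.ages
    )
    return PadBiasCorrector().fit(pad, hc_cohort.ages)


def corrected_gm_pad(model, corrector, cohort):
    pad = compute_pad(
        model.predict(cohort.tables["GM"], cohort.sex_codes), cohort.ages
    )
    return corrector.transform(pad, cohort.ages)


@pytest.fixture(scope="session")
def norm_reference(traj):
    """Large reference population for normative-calibration checks."""
    return generate_normative_population(2000, traj, seed=10)


@pytest.fixture(scope="session")
def gm_norms(norm_reference):
    """GP normative model set for the GM panel."""
    return NormativeModelSet(seed=5).fit(
        norm_reference.tables["GM"], norm_reference.ages, norm_reference.sex_codes
    )


@pytest.fixture(scope="session")
def norm_holdout(traj):
    """Held-out sample from the same normative population."""
    return generate_normative_population(2000, traj, seed=11, id_prefix="hold")
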