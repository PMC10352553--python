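import numpy as np
import pandas as pd
import pytest

from episcore import (
    CohortSimConfig,
    InvitroSimConfig,
    beta_to_m,
    compute_score,
    default_panel,
    differential_methylation,
    simulate_cohort,
    simulate_invitro,
)


@pytest.fixture(scope="session")
def panel():
    """The 200-CpG stand-in panel used throughout the suite."""
    return default_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    """One default synthetic cohort (n=2000, seed 0), shared read-only."""
    return simulate_cohort(CohortSimConfig(panel=panel))


@pytest.fixture(scope="session")
def cohort_scored(cohort, panel):
    """Phenotypes with the standardized panel score attached."""
    meth, pheno, def_base, def_fu, truth = cohort
    sv = compute_score(beta_to_m(meth), panel)
    data = pheno.copy()
    data["score"] = pd.Series(sv.standardized, index=sv.sample_ids)
    return data, sv, truth


@pytest.fixture(scope="session")
def invitro(panel):
    """Default synthetic in-vitro experiment (4 treatments x 4 replicates)."""
    return simulate_invitro(InvitroSimConfig(panel=panel))


@pytest.fixture(scope="session")
def crp_contrast(invitro):
    """CRP vs mock moderated differential methylation on the default run."""
    experiment, _truth = invitro
    return differential_methylation(experiment, treatment="CRP", reference="mock")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
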