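import numpy as np
import pandas as pd
import pytest

from rsmrpipe.synthetic import (
    BENEFICIARY_COLUMNS,
    INPATIENT_COLUMNS,
    ENCOUNTER_COLUMNS,
    ClaimsBundle,
    SimulationConfig,
    generate_dataset,
)


def make_bene(bid, *, birth=0, sex="F", ffs_start=-400, ffs_end=99999,
              mc=(np.nan, np.nan), death=np.nan):
    return dict(zip(BENEFICIARY_COLUMNS,
                    [bid, birth, sex, ffs_start, ffs_end, mc[0], mc[1], death]))


def make_claim(cid, bid, hosp, admit, discharge, principal="486",
               secondary="", procedures="", disposition="alive"):
    return dict(zip(INPATIENT_COLUMNS,
                    [cid, bid, hosp, admit, discharge, principal, secondary,
                     procedures, disposition]))


def bundle_from(benes, claims, encounters=()):
    return ClaimsBundle(
        beneficiaries=pd.DataFrame(list(benes), columns=BENEFICIARY_COLUMNS),
        inpatient=pd.DataFrame(list(claims), columns=INPATIENT_COLUMNS),
        encounters=pd.DataFrame(list(encounters), columns=ENCOUNTER_COLUMNS),
    )


def birth_for_age(age_years: float, admit: int) -> int:
    return admit - int(round(age_years * 365.25))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest bundle with transfers and planted exclusion cases."""
    cfg = SimulationConfig(
        n_hospitals=40,
        seed=20260101,
        exclusion_rates={
            "managed_care": 8,
            "incomplete_lookback": 6,
            "secondary_only": 5,
            "first_day_live": 7,
            "first_day_ama": 3,
            "under_age": 4,
            "readmission": 5,
            "transfer_chain": 5,
        },
    )
    bundle, truth = generate_dataset(cfg)
    return cfg, bundle, truth


def simulate_logistic(seed, n_hospitals, per_hospital, mu, beta, tau, prevalences):
    """Direct draw from the random-intercept logistic law (test-side oracle
    data source, independent of the claims generator)."""
    rng = np.random.default_rng(seed)
    n = n_hospitals * per_hospital
    groups = np.repeat(np.arange(n_hospitals), per_hospital)
    alpha = rng.normal(0.0, tau, n_hospitals) if tau > 0 else np.zeros(n_hospitals)
    beta = np.asarray(beta, dtype=float)
    X = (rng.random((n, len(beta))) < np.asarray(prevalences)).astype(float)
    eta = mu + X @ beta + alpha[groups]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y, groups, alpha
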