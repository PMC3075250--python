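"""Synthetic Medicare-style claims generator with known ground truth.

Emulates the data universe behind claims-based hospital profiling of 30-day
pneumonia mortality: hospitals with latent quality effects (random intercepts
on the log-odds scale), a right-skewed annual-volume distribution, patient
case mix driving a logistic mortality outcome, prior-year encounter histories
that emit mapped diagnosis codes, transfer chains, and records engineered to
trigger each cohort exclusion rule.

Every dataset is fully reproducible from its seed, and the generator returns
the ground truth (true coefficients, true hospital effects, true per-patient
event probabilities, true condition indicators) so each downstream stage can
be tested for exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "VolumeLaw",
    "SimulationConfig",
    "SyntheticTruth",
    "ClaimsBundle",
    "generate_dataset",
    "plant_exclusion_cases",
    "DEFAULT_CATEGORY_PREVALENCES",
    "DEFAULT_BETA",
]

#: Day offsets are counted from a fixed epoch: day 0 is the first day of the
#: year preceding the study year, so index admissions in [365, 699] always
#: have a complete 12-month (365-day) lookback inside the data window.
EPOCH_NOTE = "day 0 = Jan 1 of the year before the study year"

INDEX_ADMIT_LO = 365
INDEX_ADMIT_HI = 699

#: Default comorbidity prevalences for the candidate condition categories.
#: The categories are the synthetic stand-ins for HCC-style condition groups
#: (see :func:`rsmrpipe.covariates.default_mapping`); prevalences span the
#: common (heart failure, COPD) to the rare (liver disease) range seen in
#: elderly pneumonia cohorts.
DEFAULT_CATEGORY_PREVALENCES: dict[str, float] = {
    "CHF": 0.35,
    "COPD": 0.30,
    "ASTHMA": 0.08,
    "DIAB": 0.25,
    "RENAL": 0.12,
    "CANCER_META": 0.05,
    "STROKE": 0.10,
    "DEMENTIA": 0.15,
    "ARRHY": 0.20,
    "LIVER": 0.02,
    "MALNUT": 0.06,
    "VASC": 0.09,
}

#: Default true log-odds effects, first entry the national intercept mu.
#: mu = -2.27 is calibrated so that, under the default prevalences, age/sex
#: effects and tau = 0.4, the *marginal* cohort mortality sits at the
#: ~15.1% unadjusted 30-day level typical of elderly pneumonia cohorts.
#: Condition effects span protective (asthma/COPD, an empirically observed
#: inversion in pneumonia cohorts) to strongly adverse (metastatic cancer,
#: malnutrition).
DEFAULT_BETA: dict[str, float] = {
    "(mu)": -2.27,
    "CHF": 0.45,
    "COPD": -0.15,
    "ASTHMA": -0.25,
    "DIAB": 0.10,
    "RENAL": 0.40,
    "CANCER_META": 0.90,
    "STROKE": 0.25,
    "DEMENTIA": 0.50,
    "ARRHY": 0.20,
    "LIVER": 0.55,
    "MALNUT": 0.70,
    "VASC": 0.15,
}

DEFAULT_EXCLUSION_RATES: dict[str, float] = {
    "managed_care": 0.0,
    "incomplete_lookback": 0.0,
    "secondary_only": 0.0,
    "first_day_live": 0.0,
    "first_day_ama": 0.0,
    "under_age": 0.0,
    "readmission": 0.0,
    "transfer_chain": 0.0,
}

PLANT_RULES = tuple(DEFAULT_EXCLUSION_RATES)

QUALIFYING_PRINCIPAL_CODES = (
    "481",
    "482.0",
    "482.41",
    "482.9",
    "483.0",
    "485",
    "486",
    "487.0",
)

#: Principal code used to plant "pneumonia secondary only" admissions
#: (septicemia, explicitly outside the qualifying principal code set).
NON_PNEUMONIA_PRINCIPAL = "038.9"


@dataclass(frozen=True)
class VolumeLaw:
    """Annual pneumonia-volume distribution across hospitals.

    ``kind="lognormal"`` draws volumes from a lognormal law fitted to a
    target median and interquartile range (default median 37, quartiles
    18/67 — the skewed volume profile typical of US acute-care hospitals);
    ``kind="fixed"`` gives every hospital exactly ``fixed`` patients, which
    simulation studies of the estimator use for balanced designs.
    """

    kind: str = "lognormal"
    median: float = 37.0
    q1: float = 18.0
    q3: float = 67.0
    fixed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "fixed"):
            raise ValueError(f"unknown volume law kind: {self.kind!r}")
        if self.kind == "fixed":
            if self.fixed is None or self.fixed < 1:
                raise ValueError("fixed volume law requires fixed >= 1")
        elif not (0 < self.q1 <= self.median <= self.q3):
            raise ValueError("require 0 < q1 <= median <= q3")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, int(self.fixed), dtype=np.int64)
        # quartiles of a lognormal sit at median * exp(+-0.6745 sigma)
        sigma = (np.log(self.q3) - np.log(self.q1)) / (2 * 0.674490)
        draws = rng.lognormal(mean=np.log(self.median), sigma=sigma, size=n)
        return np.maximum(np.rint(draws).astype(np.int64), 1)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims universe.

    ``beta`` maps covariate names to true log-odds effects; its first entry,
    keyed ``"(mu)"``, is the national intercept. The remaining keys must
    match ``covariate_prevalences``. The mortality law for patient *i* in
    hospital *h* is Bernoulli with

        logit p_i = mu + x_i . beta + alpha_h,   alpha_h ~ Normal(0, tau^2).

    ``lookback_emission`` is the probability that each true condition leaves
    at least one mapped diagnosis code in the 12 months of prior-year
    encounters; ``index_emission`` the probability it also appears among the
    index admission's secondary codes. ``exclusion_rates`` drive
    :func:`plant_exclusion_cases` and default to all-zero (no planting).
    """

    n_hospitals: int = 100
    volume_law: VolumeLaw = field(default_factory=VolumeLaw)
    tau: float = 0.4
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PREVALENCES)
    )
    lookback_emission: float = 0.85
    index_emission: float = 0.50
    transfer_rate: float = 0.03
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES)
    )
    age_coef: float = 0.04  # per year above 80, log-odds (OR ~1.5/decade)
    female_coef: float = -0.10
    age_mean: float = 80.2
    age_sd: float = 8.0
    p_female: float = 0.558
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        names = list(self.beta)
        if not names or names[0] != "(mu)":
            raise ValueError('beta must start with the national intercept "(mu)"')
        if names[1:] != list(self.covariate_prevalences):
            raise ValueError("beta keys (after mu) must match covariate_prevalences")
        for p in list(self.covariate_prevalences.values()) + [
            self.lookback_emission,
            self.index_emission,
            self.transfer_rate,
            self.p_female,
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        for rule, r in self.exclusion_rates.items():
            if rule not in PLANT_RULES:
                raise ValueError(f"unknown exclusion rule: {rule!r}")
            if r < 0:
                raise ValueError("exclusion rates must be >= 0")
        if not all(np.isfinite(list(self.beta.values()))):
            raise ValueError("non-finite coefficient in beta")

    @property
    def mu(self) -> float:
        return float(self.beta["(mu)"])

    @property
    def categories(self) -> list[str]:
        return list(self.covariate_prevalences)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated bundle.

    ``true_conditions`` is the exact patient x category indicator matrix the
    covariate stage should recover when code emission is certain;
    ``planted`` labels every record added by :func:`plant_exclusion_cases`
    with the rule it is meant to trigger.
    """

    true_beta: pd.Series
    true_tau: float
    true_alpha_by_hospital: pd.Series
    true_event_probability_by_patient: pd.Series
    true_conditions: pd.DataFrame
    planted: pd.DataFrame

    def copy(self) -> "SyntheticTruth":
        return SyntheticTruth(
            self.true_beta.copy(),
            self.true_tau,
            self.true_alpha_by_hospital.copy(),
            self.true_event_probability_by_patient.copy(),
            self.true_conditions.copy(),
            self.planted.copy(),
        )


BENEFICIARY_COLUMNS = [
    "beneficiary_id",
    "birth_day",
    "sex",
    "ffs_start",
    "ffs_end",
    "mc_start",
    "mc_end",
    "death_day",
]
INPATIENT_COLUMNS = [
    "claim_id",
    "beneficiary_id",
    "hospital_id",
    "admission_day",
    "discharge_day",
    "principal_dx",
    "secondary_dx",
    "procedure_codes",
    "disposition",
]
ENCOUNTER_COLUMNS = ["beneficiary_id", "day", "codes", "setting"]

DISPOSITIONS = ("alive", "dead", "ama", "transferred")
SETTINGS = ("inpatient", "institutional-outpatient", "physician")


@dataclass
class ClaimsBundle:
    """Linked claims tables: beneficiaries, inpatient claims, encounters.

    Dates are integer day offsets (day 0 = start of the year before the
    study year); intervals are closed. Code lists are stored as
    semicolon-joined strings so the tables round-trip through delimited
    text unchanged.
    """

    beneficiaries: pd.DataFrame
    inpatient: pd.DataFrame
    encounters: pd.DataFrame

    def validate(self) -> None:
        missing = set(BENEFICIARY_COLUMNS) - set(self.beneficiaries.columns)
        if missing:
            raise ValueError(f"beneficiaries table missing columns: {sorted(missing)}")
        missing = set(INPATIENT_COLUMNS) - set(self.inpatient.columns)
        if missing:
            raise ValueError(f"inpatient table missing columns: {sorted(missing)}")
        missing = set(ENCOUNTER_COLUMNS) - set(self.encounters.columns)
        if missing:
            raise ValueError(f"encounters table missing columns: {sorted(missing)}")
        if (self.inpatient["discharge_day"] < self.inpatient["admission_day"]).any():
            raise ValueError("discharge before admission")
        bad = ~self.inpatient["disposition"].isin(DISPOSITIONS)
        if bad.any():
            ids = self.inpatient.loc[bad, "claim_id"].tolist()[:5]
            raise ValueError(f"unknown disposition on claims {ids}")
        known = set(self.beneficiaries["beneficiary_id"])
        orphan = ~self.inpatient["beneficiary_id"].isin(known)
        if orphan.any():
            ids = self.inpatient.loc[orphan, "claim_id"].tolist()[:5]
            raise ValueError(f"claims reference unknown beneficiaries: {ids}")

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.beneficiaries.copy(), self.inpatient.copy(), self.encounters.copy()
        )


def join_codes(codes: Sequence[str]) -> str:
    return ";".join(codes)


def split_codes(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return str(cell).split(";")


def _category_codes() -> dict[str, list[str]]:
    # local import: covariates holds the code->category vocabulary
    from .covariates import default_mapping

    return default_mapping().codes_by_category()


def generate_dataset(config: SimulationConfig) -> tuple[ClaimsBundle, SyntheticTruth]:
    """Generate a claims bundle and its ground truth from ``config``.

    Exclusion-triggering records are planted afterwards (at the configured
    rates) via :func:`plant_exclusion_cases`; call sites wanting a pristine
    bundle leave ``exclusion_rates`` at zero.
    """
    rng = np.random.default_rng(config.seed)
    cats = config.categories
    beta_vec = np.array([config.beta[c] for c in cats])
    mu = config.mu

    volumes = config.volume_law.sample(config.n_hospitals, rng)
    n = int(volumes.sum())
    hospital_ids = np.array([f"H{i:04d}" for i in range(config.n_hospitals)])
    hosp_idx = np.repeat(np.arange(config.n_hospitals), volumes)

    alpha = rng.normal(0.0, config.tau, size=config.n_hospitals) if config.tau > 0 else np.zeros(config.n_hospitals)

    a, b = (66 - config.age_mean) / config.age_sd, (110 - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    female = rng.random(n) < config.p_female
    prev = np.array([config.covariate_prevalences[c] for c in cats])
    x = (rng.random((n, len(cats))) < prev).astype(np.int8)

    eta = mu + x @ beta_vec + config.age_coef * (age - 80.0) + config.female_coef * female + alpha[hosp_idx]
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor; check beta/config")
    p = expit(eta)
    died = rng.random(n) < p

    bene_ids = np.array([f"B{i:06d}" for i in range(n)])
    admit = rng.integers(INDEX_ADMIT_LO, INDEX_ADMIT_HI + 1, size=n)
    los = 2 + rng.poisson(4.0, size=n)
    discharge = admit + los
    death_day = np.where(died, admit + rng.integers(0, 31, size=n), -1)

    is_transfer = rng.random(n) < config.transfer_rate

    cat_codes = _category_codes()
    principal = rng.choice(np.array(QUALIFYING_PRINCIPAL_CODES), size=n)

    # index secondary codes: each true condition appears with prob index_emission
    sec_mask = (x == 1) & (rng.random(x.shape) < config.index_emission)
    secondary = [[] for _ in range(n)]
    rows, cols = np.nonzero(sec_mask)
    for i, j in zip(rows, cols):
        pool = cat_codes.get(cats[j])  # categories outside the vocabulary emit nothing
        if pool:
            secondary[i].append(pool[rng.integers(len(pool))])

    claims: list[tuple] = []
    claim_counter = 0

    def next_claim_id() -> str:
        nonlocal claim_counter
        claim_counter += 1
        return f"C{claim_counter:07d}"

    for i in range(n):
        h = hospital_ids[hosp_idx[i]]
        dd = death_day[i]
        if not is_transfer[i]:
            disp = "dead" if (dd >= 0 and dd <= discharge[i]) else "alive"
            claims.append(
                (next_claim_id(), bene_ids[i], h, int(admit[i]), int(discharge[i]),
                 principal[i], join_codes(secondary[i]), "", disp)
            )
        else:
            d1 = int(admit[i]) + 2 + int(rng.poisson(1.0))
            gap = int(rng.integers(0, 2))  # 0 or 1 day: a true transfer
            a2 = d1 + gap
            d2 = a2 + 2 + int(rng.poisson(3.0))
            h2 = hospital_ids[int(rng.integers(config.n_hospitals))]
            if h2 == h:
                h2 = hospital_ids[(hosp_idx[i] + 1) % config.n_hospitals]
            disp2 = "dead" if (dd >= 0 and dd <= d2) else "alive"
            claims.append(
                (next_claim_id(), bene_ids[i], h, int(admit[i]), d1,
                 principal[i], join_codes(secondary[i]), "", "transferred")
            )
            # receiving claim copies the pneumonia principal diagnosis
            claims.append(
                (next_claim_id(), bene_ids[i], h2, a2, d2, principal[i], "", "", disp2)
            )

    inpatient = pd.DataFrame(claims, columns=INPATIENT_COLUMNS)

    # prior-year encounters: each true condition emits, with prob
    # lookback_emission, one encounter carrying a code from its category
    enc_rows: list[tuple] = []
    emit = (x == 1) & (rng.random(x.shape) < config.lookback_emission)
    rows, cols = np.nonzero(emit)
    for i, j in zip(rows, cols):
        pool = cat_codes.get(cats[j])
        if not pool:
            continue
        code = pool[rng.integers(len(pool))]
        day = int(admit[i]) - int(rng.integers(1, 366))  # in [admit-365, admit-1]
        setting = SETTINGS[rng.integers(len(SETTINGS))]
        enc_rows.append((bene_ids[i], day, code, setting))
    encounters = pd.DataFrame(enc_rows, columns=ENCOUNTER_COLUMNS)

    birth = admit - np.rint(age * 365.25).astype(np.int64)
    beneficiaries = pd.DataFrame(
        {
            "beneficiary_id": bene_ids,
            "birth_day": birth,
            "sex": np.where(female, "F", "M"),
            "ffs_start": np.zeros(n, dtype=np.int64) - 400,
            "ffs_end": np.full(n, 99999, dtype=np.int64),
            "mc_start": np.full(n, np.nan),
            "mc_end": np.full(n, np.nan),
            "death_day": np.where(death_day >= 0, death_day, np.nan),
        }
    )

    bundle = ClaimsBundle(beneficiaries, inpatient, encounters)
    bundle.validate()

    truth = SyntheticTruth(
        true_beta=pd.Series(dict(config.beta)),
        true_tau=config.tau,
        true_alpha_by_hospital=pd.Series(alpha, index=hospital_ids),
        true_event_probability_by_patient=pd.Series(p, index=bene_ids),
        true_conditions=pd.DataFrame(x, index=bene_ids, columns=cats),
        planted=pd.DataFrame(columns=["rule", "beneficiary_id", "claim_id"]),
    )

    if any(r > 0 for r in config.exclusion_rates.values()):
        bundle, planted = plant_exclusion_cases(bundle, config)
        truth.planted = planted
    return bundle, truth


def _plant_counts(rates: Mapping[str, float], n_base: int) -> dict[str, int]:
    """Rates < 1 are fractions of the base cohort; values >= 1 are counts."""
    out = {}
    for rule, r in rates.items():
        out[rule] = int(r) if r >= 1 else int(round(r * n_base))
    return out


def plant_exclusion_cases(
    bundle: ClaimsBundle, config: SimulationConfig
) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Add records that exercise each cohort exclusion rule.

    Returns the augmented bundle and a ``planted`` table labelling every
    added/modified record with the rule it should trigger downstream
    (``managed_care``, ``incomplete_lookback``, ``secondary_only``,
    ``first_day_live``, ``first_day_ama`` (retained by design),
    ``under_age``, ``readmission`` (two episodes, gap >= 2 days),
    ``transfer_chain`` (one merged episode, gap <= 1 day)).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    bundle = bundle.copy()
    bene = bundle.beneficiaries
    inpat = bundle.inpatient
    counts = _plant_counts(config.exclusion_rates, len(bene))
    planted: list[tuple] = []

    # modify existing single-claim beneficiaries for enrollment rules
    # (transfer patients are skipped so one planted label = one admission)
    claim_counts = inpat.groupby("beneficiary_id").size()
    eligible = claim_counts.index[claim_counts == 1].to_numpy().copy()
    rng.shuffle(eligible)
    cursor = 0

    claim_seq = len(inpat) + 1
    bene_seq = len(bene) + 1
    new_benes: list[tuple] = []
    new_claims: list[tuple] = []

    def fresh_bene(age_years: float, death: float = np.nan) -> str:
        nonlocal bene_seq
        bid = f"P{bene_seq:06d}"
        bene_seq += 1
        return bid

    def fresh_claim_id() -> str:
        nonlocal claim_seq
        cid = f"C{claim_seq:07d}"
        claim_seq += 1
        return cid

    admit_of = inpat.groupby("beneficiary_id")["admission_day"].min()

    k = counts.get("managed_care", 0)
    for bid in eligible[cursor : cursor + k]:
        t0 = int(admit_of.get(bid, 500))
        bene.loc[bene["beneficiary_id"] == bid, ["mc_start", "mc_end"]] = [
            float(t0 - 200),
            float(t0 - 100),
        ]
        planted.append(("managed_care", bid, None))
    cursor += k

    k = counts.get("incomplete_lookback", 0)
    for bid in eligible[cursor : cursor + k]:
        t0 = int(admit_of.get(bid, 500))
        bene.loc[bene["beneficiary_id"] == bid, "ffs_start"] = t0 - 100
        planted.append(("incomplete_lookback", bid, None))
    cursor += k

    def add_new_admission(rule: str, *, age: float, principal: str,
                          secondary: str = "", los: int = 5,
                          disposition: str = "alive") -> None:
        bid = fresh_bene(age)
        t0 = int(rng.integers(INDEX_ADMIT_LO, INDEX_ADMIT_HI + 1))
        cid = fresh_claim_id()
        h = f"H{int(rng.integers(config.n_hospitals)):04d}"
        new_benes.append(
            (bid, t0 - int(round(age * 365.25)), "F" if rng.random() < 0.5 else "M",
             -400, 99999, np.nan, np.nan, np.nan)
        )
        new_claims.append(
            (cid, bid, h, t0, t0 + los, principal, secondary, "", disposition)
        )
        planted.append((rule, bid, cid))

    for _ in range(counts.get("secondary_only", 0)):
        add_new_admission("secondary_only", age=78.0,
                          principal=NON_PNEUMONIA_PRINCIPAL, secondary="486")
    for _ in range(counts.get("first_day_live", 0)):
        add_new_admission("first_day_live", age=75.0, principal="486",
                          los=1, disposition="alive")
    for _ in range(counts.get("first_day_ama", 0)):
        add_new_admission("first_day_ama", age=75.0, principal="486",
                          los=1, disposition="ama")
    for _ in range(counts.get("under_age", 0)):
        add_new_admission("under_age", age=60.0, principal="486")

    def add_chain(rule: str, gap: int) -> None:
        bid = fresh_bene(79.0)
        t0 = int(rng.integers(INDEX_ADMIT_LO, INDEX_ADMIT_HI - 40))
        h1 = f"H{int(rng.integers(config.n_hospitals)):04d}"
        h2 = f"H{(int(rng.integers(config.n_hospitals)) + 1) % config.n_hospitals:04d}"
        new_benes.append((bid, t0 - 29000, "F", -400, 99999, np.nan, np.nan, np.nan))
        d1 = t0 + 4
        c1, c2 = fresh_claim_id(), fresh_claim_id()
        disp1 = "transferred" if gap <= 1 else "alive"
        new_claims.append((c1, bid, h1, t0, d1, "486", "", "", disp1))
        a2 = d1 + gap
        new_claims.append((c2, bid, h2, a2, a2 + 5, "486", "", "", "alive"))
        planted.append((rule, bid, c1))
        planted.append((rule, bid, c2))

    for _ in range(counts.get("transfer_chain", 0)):
        add_chain("transfer_chain", gap=1)
    for _ in range(counts.get("readmission", 0)):
        add_chain("readmission", gap=3)

    if new_benes:
        bundle.beneficiaries = pd.concat(
            [bene, pd.DataFrame(new_benes, columns=BENEFICIARY_COLUMNS)],
            ignore_index=True,
        )
    if new_claims:
        bundle.inpatient = pd.concat(
            [inpat, pd.DataFrame(new_claims, columns=INPATIENT_COLUMNS)],
            ignore_index=True,
        )
    bundle.validate()
    planted_df = pd.DataFrame(planted, columns=["rule", "beneficiary_id", "claim_id"])
    return bundle, planted_df
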