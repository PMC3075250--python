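"""Cohort construction: inclusion/exclusion, transfer linkage, outcome.

The analytic unit is the *episode of care*: one or more transfer-linked
inpatient admissions, attributed to the initial (index) hospital and
carrying a 30-day all-cause mortality outcome counted from the index
admission date. Exclusion rules are applied in a fixed, documented
precedence so that the audit tally attributes each dropped admission to
exactly one rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import ClaimsBundle, split_codes

__all__ = [
    "CohortSpec",
    "ExclusionTally",
    "apply_inclusion_exclusion",
    "link_transfers",
    "attach_outcome",
    "select_one_episode_per_patient",
    "split_cohort",
    "build_cohort",
]

DEFAULT_PRINCIPAL_CODES = ("481", "482*", "483*", "485", "486", "487.0")
VIRAL_CODES = ("480.0", "480.1", "480.2")

#: Exclusion precedence: each candidate admission is tallied against the
#: first failing rule, in this order.
EXCLUSION_ORDER = (
    "under_age",
    "incomplete_lookback",
    "managed_care",
    "secondary_only",
    "first_day_live",
)

OUTCOME_WINDOW_DAYS = 30


@dataclass(frozen=True)
class CohortSpec:
    """Cohort definition parameters.

    ``principal_code_set`` patterns match discharge diagnosis codes; a
    trailing ``*`` makes a pattern a prefix match (the default set covers
    bacterial pneumonia 481, 482.XX, 483.X, 485, 486 and influenza with
    pneumonia 487.0; ``include_viral_codes`` adds 480.0/480.1/480.2).
    ``transfer_max_gap_days`` is the largest admission-to-prior-discharge
    gap still counted as a transfer (1 day); larger gaps are readmissions.
    """

    principal_code_set: tuple[str, ...] = DEFAULT_PRINCIPAL_CODES
    include_viral_codes: bool = False
    min_age_years: int = 66
    lookback_months: int = 12
    transfer_max_gap_days: int = 1
    sameday_discharge_exclusion: bool = True
    transfer_match_principal_only: bool = False
    split_fraction: float = 0.5
    stratify_by_hospital: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.principal_code_set:
            raise ValueError("principal_code_set must be non-empty")
        if not 0 < self.split_fraction <= 1:
            raise ValueError("split_fraction must be in (0, 1]")

    @property
    def code_patterns(self) -> tuple[str, ...]:
        pats = self.principal_code_set
        if self.include_viral_codes:
            pats = pats + VIRAL_CODES
        return pats

    @property
    def lookback_days(self) -> int:
        return round(self.lookback_months * 365 / 12)


def matches_code_set(code: str, patterns: Sequence[str]) -> bool:
    code = str(code).strip()
    for pat in patterns:
        if pat.endswith("*"):
            if code.startswith(pat[:-1]):
                return True
        elif code == pat:
            return True
    return False


@dataclass
class ExclusionTally:
    """Per-rule exclusion counts plus the included count.

    Conservation invariant: ``included + sum(excluded) == candidates``,
    where candidates are admissions carrying a qualifying pneumonia code
    in any diagnosis position.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_ORDER + ("multiple_admission",)}
    )
    included: int = 0

    @property
    def total_candidates(self) -> int:
        return self.included + sum(self.counts.values())

    def as_frame(self) -> pd.DataFrame:
        rows = [("included", self.included)] + list(self.counts.items())
        return pd.DataFrame(rows, columns=["rule", "count"])


def _age_years(birth_day: int, admit_day: int) -> float:
    return (admit_day - birth_day) / 365.25


def apply_inclusion_exclusion(
    bundle: ClaimsBundle, spec: CohortSpec
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the admission-level inclusion/exclusion rules.

    Candidates are inpatient claims with a qualifying pneumonia code in any
    position. In precedence order, an admission is excluded when the
    patient is under the age floor at admission; when fee-for-service
    enrollment does not cover the full lookback window through admission;
    when a managed-care interval overlaps that window; when pneumonia
    appears only as a secondary diagnosis; or when the patient was
    discharged alive, not against medical advice, within the first day of
    admission (transfer-out dispositions are retained by this rule, as are
    in-hospital deaths).

    Returns the retained admissions (with ``age_years`` appended) and the
    audit tally.
    """
    bundle.validate()
    pats = spec.code_patterns
    bene = bundle.beneficiaries.set_index("beneficiary_id")
    tally = ExclusionTally()
    retained = []
    for _, claim in bundle.inpatient.iterrows():
        principal_ok = matches_code_set(claim["principal_dx"], pats)
        secondary_ok = any(
            matches_code_set(c, pats) for c in split_codes(claim["secondary_dx"])
        )
        if not (principal_ok or secondary_ok):
            continue  # not a pneumonia candidate at all
        b = bene.loc[claim["beneficiary_id"]]
        t0 = int(claim["admission_day"])
        age = _age_years(int(b["birth_day"]), t0)
        lb_start = t0 - spec.lookback_days
        if math.floor(age) < spec.min_age_years:
            tally.counts["under_age"] += 1
            continue
        if not (b["ffs_start"] <= lb_start and b["ffs_end"] >= t0):
            tally.counts["incomplete_lookback"] += 1
            continue
        if not pd.isna(b["mc_start"]):
            if b["mc_start"] <= t0 and b["mc_end"] >= lb_start:
                tally.counts["managed_care"] += 1
                continue
        if not principal_ok:
            tally.counts["secondary_only"] += 1
            continue
        stay = int(claim["discharge_day"]) - t0
        if (
            spec.sameday_discharge_exclusion
            and claim["disposition"] == "alive"
            and stay <= 1
        ):
            tally.counts["first_day_live"] += 1
            continue
        rec = claim.to_dict()
        rec["age_years"] = age
        retained.append(rec)
        tally.included += 1

    cols = list(bundle.inpatient.columns) + ["age_years"]
    out = pd.DataFrame(retained, columns=cols)
    return out, tally


def link_transfers(admissions: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Merge same-beneficiary admissions into transfer episodes.

    Consecutive admissions merge iff the next admission begins no more than
    ``transfer_max_gap_days`` after the previous discharge and both claims
    carry a qualifying pneumonia diagnosis (any position by default;
    principal-only behind ``transfer_match_principal_only``). Merging is
    transitive along a chain. Overlapping same-beneficiary stays are an
    error (ambiguous chain). The first admission supplies the index
    hospital and index admission date.
    """
    pats = spec.code_patterns

    def qualifies(row) -> bool:
        if matches_code_set(row.principal_dx, pats):
            return True
        if spec.transfer_match_principal_only:
            return False
        return any(matches_code_set(c, pats) for c in split_codes(row.secondary_dx))

    episodes = []
    seq = 0
    ordered = admissions.sort_values(
        ["beneficiary_id", "admission_day", "claim_id"], kind="mergesort"
    )
    for bid, grp in ordered.groupby("beneficiary_id", sort=False):
        rows = list(grp.itertuples(index=False))
        chain = [rows[0]]
        for prev, nxt in zip(rows, rows[1:]):
            if nxt.admission_day < prev.discharge_day:
                raise ValueError(
                    f"overlapping stays for {bid}: claims "
                    f"{prev.claim_id}, {nxt.claim_id} (ambiguous chain)"
                )
            gap = nxt.admission_day - prev.discharge_day
            if gap <= spec.transfer_max_gap_days and qualifies(prev) and qualifies(nxt):
                chain.append(nxt)
            else:
                episodes.append((bid, chain))
                chain = [nxt]
        episodes.append((bid, chain))
        seq += 1

    out_rows = []
    for i, (bid, chain) in enumerate(episodes):
        first = chain[0]
        out_rows.append(
            {
                "episode_id": f"E{i:07d}",
                "beneficiary_id": bid,
                "hospital_id": first.hospital_id,
                "index_admission_day": int(first.admission_day),
                "episode_discharge_day": int(chain[-1].discharge_day),
                "claim_ids": ";".join(c.claim_id for c in chain),
                "n_claims": len(chain),
                "age_years": float(first.age_years),
            }
        )
    return pd.DataFrame(
        out_rows,
        columns=[
            "episode_id",
            "beneficiary_id",
            "hospital_id",
            "index_admission_day",
            "episode_discharge_day",
            "claim_ids",
            "n_claims",
            "age_years",
        ],
    )


def attach_outcome(episodes: pd.DataFrame, bundle: ClaimsBundle) -> pd.DataFrame:
    """30-day all-cause mortality from the index admission date.

    outcome = 1 iff death date <= index admission + 30 days; a missing
    death date is survival. A death date before the index admission is a
    data error.
    """
    bene = bundle.beneficiaries.set_index("beneficiary_id")
    death = bene["death_day"].reindex(episodes["beneficiary_id"]).to_numpy()
    t0 = episodes["index_admission_day"].to_numpy()
    with np.errstate(invalid="ignore"):
        before = death < t0
    if np.any(np.nan_to_num(before, nan=False)):
        bad = episodes.loc[np.where(before)[0][:5], "beneficiary_id"].tolist()
        raise ValueError(f"death date before index admission for {bad}")
    outcome = np.where(np.isnan(death), 0, (death <= t0 + OUTCOME_WINDOW_DAYS)).astype(int)
    out = episodes.copy()
    out["outcome"] = outcome
    return out


def select_one_episode_per_patient(episodes: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one episode per beneficiary, chosen uniformly at random.

    Reproducible from ``seed``; beneficiaries with a single episode pass
    through unchanged.
    """
    if len(episodes) == 0:
        return episodes.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    ordered = episodes.sort_values("episode_id", kind="mergesort").reset_index(drop=True)
    key = rng.random(len(ordered))
    pick = pd.Series(key).groupby(ordered["beneficiary_id"]).idxmin()
    return ordered.loc[sorted(pick)].reset_index(drop=True)


def split_cohort(
    cohort: pd.DataFrame, spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hospital-stratified random derivation/validation split.

    Per hospital, ``ceil(split_fraction * n)`` episodes go to derivation,
    so a single-case hospital lands in derivation and every hospital is
    represented there where possible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 130363]))
    der_idx: list[int] = []
    ordered = cohort.sort_values("episode_id", kind="mergesort").reset_index(drop=True)
    if spec.stratify_by_hospital:
        groups = ordered.groupby("hospital_id", sort=True).indices.items()
    else:
        groups = [("all", np.arange(len(ordered)))]
    for _, idx in groups:
        idx = np.asarray(idx)
        n_der = math.ceil(spec.split_fraction * len(idx))
        perm = rng.permutation(len(idx))
        der_idx.extend(idx[perm[:n_der]])
    mask = np.zeros(len(ordered), dtype=bool)
    mask[der_idx] = True
    return (
        ordered[mask].reset_index(drop=True),
        ordered[~mask].reset_index(drop=True),
    )


def build_cohort(
    bundle: ClaimsBundle, spec: CohortSpec
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Full cohort construction: rules → linkage → outcome → one-per-patient.

    The tally's ``multiple_admission`` row counts episodes dropped by the
    one-admission-per-patient sampling (episodes, not raw admissions, are
    the sampled unit)."""
    admissions, tally = apply_inclusion_exclusion(bundle, spec)
    episodes = link_transfers(admissions, spec)
    episodes = attach_outcome(episodes, bundle)
    cohort = select_one_episode_per_patient(episodes, spec.seed)
    tally.counts["multiple_admission"] = len(episodes) - len(cohort)
    return cohort, tally
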