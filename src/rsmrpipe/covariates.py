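"""Condition-category mapping and risk-adjustment matrix assembly.

Diagnosis (and procedure) codes are grouped into clinically coherent
condition categories through an ordered rules table — the same aggregation
idea as CMS's Hierarchical Condition Categories, exercised here on a small
configurable vocabulary. Candidate risk-adjustment variables are assembled
per episode from the index admission's secondary/procedure codes and from
all inpatient, institutional-outpatient and physician encounters in the 12
months before the index admission, then filtered by prevalence.

Categories flagged ``complication_suspect`` may represent complications of
the index stay rather than pre-existing conditions; they are credited from
the index admission only when coded on the initial (first) claim of a
transfer episode, never from the receiving hospital.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import ClaimsBundle, split_codes

log = logging.getLogger(__name__)

__all__ = [
    "ConditionMapping",
    "CovariateMatrix",
    "default_mapping",
    "map_codes_to_categories",
    "build_candidate_matrix",
    "frequency_filter",
    "variance_inflation",
    "prepare_chart_matrix",
]

LOOKBACK_DAYS = 365  # 12 months


@dataclass(frozen=True)
class ConditionMapping:
    """Ordered code→category rules plus category-level policy flags.

    ``rules`` columns: ``pattern`` (code literal, ``*`` suffix = prefix
    match), ``match_type`` (``exact`` | ``prefix``), ``category``.
    ``combine_groups`` merges sets of categories into one model variable
    (clinical-judgment grouping, supplied as policy data, not inferred).
    ``complication_suspect`` lists categories creditable from the index
    admission only via the initial claim of the episode.
    """

    rules: pd.DataFrame
    labels: Mapping[str, str] = field(default_factory=dict)
    combine_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    complication_suspect: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        req = {"pattern", "match_type", "category"}
        if not req <= set(self.rules.columns):
            raise ValueError(f"rules table needs columns {sorted(req)}")
        bad = ~self.rules["match_type"].isin(["exact", "prefix"])
        if bad.any():
            raise ValueError("match_type must be 'exact' or 'prefix'")
        if (self.rules["pattern"].str.len() == 0).any():
            raise ValueError("empty pattern")
        cats = set(self.rules["category"])
        for g, members in self.combine_groups.items():
            unknown = set(members) - cats
            if unknown:
                raise ValueError(f"combine group {g!r} references unknown {unknown}")

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.rules["category"]))

    def model_variable(self, category: str) -> str:
        for g, members in self.combine_groups.items():
            if category in members:
                return g
        return category

    @property
    def model_variables(self) -> list[str]:
        return list(dict.fromkeys(self.model_variable(c) for c in self.categories))

    def codes_by_category(self) -> dict[str, list[str]]:
        """Exact-rule codes per category (used by the synthetic generator)."""
        out: dict[str, list[str]] = {}
        for _, r in self.rules.iterrows():
            if r["match_type"] == "exact":
                out.setdefault(r["category"], []).append(r["pattern"])
        return out

    def to_csv(self, path) -> None:
        df = self.rules.copy()
        df["combine_group"] = [
            g if (g := self.model_variable(c)) != c else ""
            for c in df["category"]
        ]
        df["complication_suspect"] = df["category"].isin(self.complication_suspect)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionMapping":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        combine: dict[str, list[str]] = {}
        suspect = set()
        for _, r in df.iterrows():
            g = r.get("combine_group", "")
            if g:
                combine.setdefault(g, [])
                if r["category"] not in combine[g]:
                    combine[g].append(r["category"])
            if str(r.get("complication_suspect", "")).lower() == "true":
                suspect.add(r["category"])
        return cls(
            rules=df[["pattern", "match_type", "category"]].copy(),
            combine_groups={g: tuple(m) for g, m in combine.items()},
            complication_suspect=frozenset(suspect),
        )


_DEFAULT_RULES = [
    # heart failure
    ("428.0", "exact", "CHF"), ("428.1", "exact", "CHF"), ("428.9", "exact", "CHF"),
    # chronic obstructive pulmonary disease
    ("491.21", "exact", "COPD"), ("492.8", "exact", "COPD"), ("496", "exact", "COPD"),
    # asthma
    ("493.90", "exact", "ASTHMA"), ("493.92", "exact", "ASTHMA"),
    # diabetes
    ("250.00", "exact", "DIAB"), ("250.02", "exact", "DIAB"), ("250.40", "exact", "DIAB"),
    # chronic kidney disease
    ("585.6", "exact", "RENAL"), ("585.9", "exact", "RENAL"), ("586", "exact", "RENAL"),
    # metastatic cancer
    ("197.0", "exact", "CANCER_META"), ("198.5", "exact", "CANCER_META"),
    ("199.1", "exact", "CANCER_META"),
    # cerebrovascular disease
    ("434.91", "exact", "STROKE"), ("436", "exact", "STROKE"),
    # dementia
    ("290.0", "exact", "DEMENTIA"), ("294.10", "exact", "DEMENTIA"),
    ("331.0", "exact", "DEMENTIA"),
    # arrhythmia
    ("427.31", "exact", "ARRHY"), ("427.1", "exact", "ARRHY"),
    # liver disease
    ("571.2", "exact", "LIVER"), ("571.5", "exact", "LIVER"),
    # protein-calorie malnutrition
    ("263.9", "exact", "MALNUT"), ("261", "exact", "MALNUT"),
    # peripheral vascular disease
    ("440.20", "exact", "VASC"), ("443.9", "exact", "VASC"),
    # potential complications of the index stay (suspect categories)
    ("518.81", "exact", "RESP_FAIL"), ("518.84", "exact", "RESP_FAIL"),
    ("785.52", "exact", "SHOCK"), ("785.59", "exact", "SHOCK"),
    ("038.*", "prefix", "SEPSIS"),
    # revascularization history from procedure codes
    ("36.1*", "prefix", "CABG_PCI"), ("00.66", "exact", "CABG_PCI"),
]

_DEFAULT_LABELS = {
    "CHF": "congestive heart failure",
    "COPD": "chronic obstructive pulmonary disease",
    "ASTHMA": "asthma",
    "DIAB": "diabetes mellitus",
    "RENAL": "chronic kidney disease",
    "CANCER_META": "metastatic cancer",
    "STROKE": "cerebrovascular disease",
    "DEMENTIA": "dementia",
    "ARRHY": "cardiac arrhythmia",
    "LIVER": "chronic liver disease",
    "MALNUT": "protein-calorie malnutrition",
    "VASC": "peripheral vascular disease",
    "RESP_FAIL": "acute respiratory failure",
    "SHOCK": "shock",
    "SEPSIS": "septicemia",
    "CABG_PCI": "bypass surgery or PCI history",
}


def default_mapping() -> ConditionMapping:
    """The packaged synthetic vocabulary: ~40 codes onto 16 categories."""
    rules = pd.DataFrame(_DEFAULT_RULES, columns=["pattern", "match_type", "category"])
    return ConditionMapping(
        rules=rules,
        labels=dict(_DEFAULT_LABELS),
        combine_groups={},
        complication_suspect=frozenset({"RESP_FAIL", "SHOCK", "SEPSIS"}),
    )


def map_codes_to_categories(
    codes: Iterable[str], mapping: ConditionMapping
) -> set[str]:
    """Union of categories matched by any code; unmapped codes are ignored
    (counted in a diagnostics log)."""
    out: set[str] = set()
    unmapped = 0
    rules = mapping.rules
    exact = {}
    prefixes: list[tuple[str, str]] = []
    for _, r in rules.iterrows():
        if r["match_type"] == "exact":
            exact.setdefault(r["pattern"], r["category"])
        else:
            prefixes.append((r["pattern"].rstrip("*"), r["category"]))
    for code in codes:
        code = str(code).strip()
        if not code:
            continue
        if code in exact:
            out.add(exact[code])
            continue
        hit = False
        for pre, cat in prefixes:
            if code.startswith(pre):
                out.add(cat)
                hit = True
        if not hit:
            unmapped += 1
    if unmapped:
        log.debug("%d codes had no mapping rule", unmapped)
    return out


@dataclass
class CovariateMatrix:
    """Episode x covariate design with column provenance.

    ``data`` holds one row per episode: ``age`` (years, continuous),
    ``female`` (0/1), then binary condition indicators. ``provenance``
    records, per indicator column, the crediting sources observed
    (``index-secondary``, ``lookback:<setting>``, ``demographic``).
    """

    data: pd.DataFrame
    provenance: pd.DataFrame  # columns: column, source

    DEMOGRAPHICS = ("age", "female")

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.DEMOGRAPHICS]

    def prevalence(self) -> pd.Series:
        return self.data[self.indicator_columns].mean()

    def copy(self) -> "CovariateMatrix":
        return CovariateMatrix(self.data.copy(), self.provenance.copy())


def _credit(sources: dict[str, set[str]], cat: str, src: str) -> None:
    sources.setdefault(cat, set()).add(src)


def build_candidate_matrix(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    mapping: ConditionMapping,
    *,
    lookback_days: int = LOOKBACK_DAYS,
) -> CovariateMatrix:
    """Assemble the candidate design for each episode in ``cohort``.

    A category indicator is set when the category is credited by

    * secondary diagnosis or procedure codes on the index admission —
      for ``complication_suspect`` categories only the episode's initial
      claim may credit, for all others any claim of the episode; or
    * any diagnosis code on an encounter dated in the half-open window
      ``[index_admission - lookback_days, index_admission)`` — index-day
      encounters are not lookback.

    Demographics (age at admission in years, female indicator) are
    appended and never subject to crediting rules. Combine groups in the
    mapping merge member categories into a single model variable.
    """
    bene = bundle.beneficiaries.set_index("beneficiary_id")
    claims = bundle.inpatient.set_index("claim_id")
    enc = bundle.encounters
    enc_by_bene = dict(tuple(enc.groupby("beneficiary_id"))) if len(enc) else {}

    variables = [
        v for v in mapping.model_variables
    ]
    rows = []
    prov: dict[str, set[str]] = {}
    for _, ep in cohort.iterrows():
        bid = ep["beneficiary_id"]
        if bid not in bene.index:
            raise KeyError(f"episode references unknown beneficiary {bid!r}")
        t0 = int(ep["index_admission_day"])
        claim_ids = str(ep["claim_ids"]).split(";")
        credited: dict[str, set[str]] = {}

        for pos, cid in enumerate(claim_ids):
            claim = claims.loc[cid]
            codes = split_codes(claim["secondary_dx"]) + split_codes(
                claim["procedure_codes"]
            )
            for cat in map_codes_to_categories(codes, mapping):
                if cat in mapping.complication_suspect and pos > 0:
                    continue  # receiving-hospital coding may be a complication
                _credit(credited, cat, "index-secondary")

        for sub in ([enc_by_bene[bid]] if bid in enc_by_bene else []):
            in_window = sub[(sub["day"] >= t0 - lookback_days) & (sub["day"] < t0)]
            for _, e in in_window.iterrows():
                for cat in map_codes_to_categories(split_codes(e["codes"]), mapping):
                    _credit(credited, cat, f"lookback:{e['setting']}")

        row = {v: 0 for v in variables}
        for cat, srcs in credited.items():
            v = mapping.model_variable(cat)
            row[v] = 1
            for s in srcs:
                _credit(prov, v, s)
        age = (t0 - int(bene.loc[bid, "birth_day"])) / 365.25
        row["age"] = age
        row["female"] = 1 if bene.loc[bid, "sex"] == "F" else 0
        rows.append(row)

    data = pd.DataFrame(rows, index=cohort["episode_id"].to_numpy())
    data = data[["age", "female"] + variables]
    prov_rows = [("age", "demographic"), ("female", "demographic")] + [
        (c, s) for c in variables for s in sorted(prov.get(c, ()))
    ]
    provenance = pd.DataFrame(prov_rows, columns=["column", "source"])
    return CovariateMatrix(data=data, provenance=provenance)


def frequency_filter(
    matrix: CovariateMatrix, threshold: float = 0.01
) -> CovariateMatrix:
    """Drop indicator columns with prevalence strictly below ``threshold``.

    A column at exactly the threshold is kept (the elimination rule is
    "frequency < threshold"). Demographics are never dropped.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    prev = matrix.prevalence()
    dropped = [c for c in matrix.indicator_columns if prev[c] < threshold]
    if dropped:
        log.info("frequency filter dropped %s", dropped)
    keep = [c for c in matrix.data.columns if c not in dropped]
    return CovariateMatrix(
        data=matrix.data[keep].copy(),
        provenance=matrix.provenance[~matrix.provenance["column"].isin(dropped)].copy(),
    )


def variance_inflation(matrix: CovariateMatrix | pd.DataFrame) -> pd.Series:
    """Per-column variance inflation factors, VIF_j = 1 / (1 - R2_j).

    R2_j is from the least-squares regression of column j on all other
    columns (with intercept). A perfectly collinear column is reported as
    ``inf``; the columns involved are named in the log.
    """
    df = matrix.data if isinstance(matrix, CovariateMatrix) else matrix
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns for VIF")
    X = df.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = [c for c, s in zip(cols, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant column(s): {const}")
    out = {}
    n = len(X)
    ones = np.ones((n, 1))
    for j, cj in enumerate(cols):
        y = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 > 1 - 1e-12:
            others = [c for k, c in enumerate(cols) if k != j]
            partners = [c for c, b in zip(others, coef[1:]) if abs(b) > 1e-8]
            log.warning("column %s exactly collinear with %s", cj, partners)
            out[cj] = np.inf
        else:
            out[cj] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def prepare_chart_matrix(
    records: pd.DataFrame, missing_threshold: float = 0.10
) -> CovariateMatrix:
    """Prepare an abstracted-record (chart) design with missing-value dummies.

    Variables whose missing rate exceeds ``missing_threshold`` are excluded
    outright. Each remaining variable with any missingness contributes its
    base column (missing entries filled with the reference value 0) plus a
    paired ``<name>_missing`` indicator, so that all available cases stay in
    the model under a missing-at-random assumption.
    """
    if len(records) == 0:
        raise ValueError("empty chart records")
    out = {}
    prov = []
    for col in records.columns:
        miss = records[col].isna()
        rate = float(miss.mean())
        if rate == 1.0:
            log.warning("chart variable %s entirely missing; excluded", col)
            continue
        if rate > missing_threshold:
            log.info("chart variable %s missing %.1f%%; excluded", col, 100 * rate)
            continue
        if rate > 0:
            out[col] = records[col].fillna(0).to_numpy(dtype=float)
            out[f"{col}_missing"] = miss.to_numpy(dtype=np.int8)
            prov.append((col, "chart"))
            prov.append((f"{col}_missing", "chart-missing-dummy"))
        else:
            out[col] = records[col].to_numpy(dtype=float)
            prov.append((col, "chart"))
    data = pd.DataFrame(out, index=records.index)
    return CovariateMatrix(
        data=data, provenance=pd.DataFrame(prov, columns=["column", "source"])
    )
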