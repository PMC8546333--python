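"""Case pipeline: from raw report tables to the analysis dataset.

Order of operations mirrors how spontaneous-reporting analyses are
actually run: deduplicate report versions (keep the latest receipt date
per case), normalise drug names, apply the case definition (suspect
roles, drug dictionary, indication filter, event-term list) and classify
outcomes into mutually exclusive severity groups.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import FaersBundle, OUTCOME_CODES, date_sort_key

__all__ = ["CaseDefinition", "deduplicate", "normalize_name", "normalize_term",
           "map_drugs", "map_drug_records", "apply_indication_filter",
           "flag_events", "classify_outcome", "age_to_years", "age_band",
           "country_to_region", "assemble_cases", "CaseConfigError"]


class CaseConfigError(ValueError):
    """Invalid case definition (e.g. ambiguous synonym)."""


REGIONS = ("North America", "Europe", "Asia", "South America",
           "Oceania", "Africa", "unknown")

AGE_BANDS = ("<18", "18-44", "45-64", "65-74", "75-84", ">85", "unknown")

#: years per age-unit code
AGE_UNIT_FACTORS = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12,
                    "WK": 1 / 52.1429, "DY": 1 / 365.25, "HR": 1 / 8766}

#: occupation codes counted as health professionals vs consumers
_HEALTH_PROFESSIONAL = {"MD", "PH", "OT", "HP", "RN"}
_CONSUMER = {"CN", "LW"}

# trailing dose/formulation tokens stripped from verbatim drug names
_UNIT_TOKENS = {"mg", "mcg", "ug", "g", "kg", "ml", "l", "dl", "iu",
                "meq", "unit", "units", "pct", "percent"}
_FORM_TOKENS = {"tablet", "tablets", "tab", "tabs", "capsule", "capsules",
                "cap", "caps", "injection", "inj", "solution", "soln",
                "syringe", "pen", "prefilled", "oral", "cream", "ointment",
                "patch", "spray", "suspension", "vial", "kit", "sc",
                "subcutaneous", "intravenous", "iv"}
_NUMERIC_RE = re.compile(r"^\d+(\.\d+)?([a-z]+)?$")
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


def normalize_term(raw: str) -> str:
    """Mild normalisation for controlled-vocabulary terms (events,
    indications): case-fold, strip punctuation, collapse whitespace."""
    return " ".join(_NON_ALNUM_RE.sub(" ", str(raw).lower()).split())


def normalize_name(raw: str) -> str:
    """Normalise a verbatim drug name for dictionary matching.

    Case-folds, trims, collapses whitespace, strips punctuation, then
    removes trailing dose/formulation tokens (bare numbers, number+unit
    composites like ``40mg``, unit words, dosage-form words).
    """
    tokens = normalize_term(raw).split()
    while tokens:
        t = tokens[-1]
        if t in _UNIT_TOKENS or t in _FORM_TOKENS or _NUMERIC_RE.match(t):
            tokens.pop()
        else:
            break
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# case definition
# ---------------------------------------------------------------------------

@dataclass
class CaseDefinition:
    """Defines cases vs non-cases for one drug family and event family.

    ``drug_dictionary`` maps a canonical drug identifier to its brand and
    generic synonyms.  ``event_terms`` is the preferred-term list standing
    in for a MedDRA PT set.  ``indication_terms`` restricts matched drug
    records to given indications; an empty set disables the filter.
    ``match_mode`` governs drug-name matching: ``exact`` (after
    normalisation, default) or ``substring``.  Event matching is exact
    term equality after normalisation unless ``event_match_mode`` is
    ``substring``.
    """
    drug_dictionary: dict[str, set[str]]
    event_terms: set[str]
    allowed_roles: set[str] = field(default_factory=lambda: {"PS", "SS"})
    indication_terms: set[str] = field(
        default_factory=lambda: {"rheumatoid arthritis"})
    match_mode: str = "exact"
    event_match_mode: str = "exact"

    def __post_init__(self) -> None:
        self.drug_dictionary = {k: set(v) for k, v in self.drug_dictionary.items()}
        self.event_terms = set(self.event_terms)
        self.allowed_roles = set(self.allowed_roles)
        self.indication_terms = set(self.indication_terms or ())
        self.validate()

    def validate(self) -> None:
        if not self.event_terms:
            raise CaseConfigError("event_terms must be non-empty")
        if self.match_mode not in ("exact", "substring"):
            raise CaseConfigError(f"unknown match_mode {self.match_mode!r}")
        if self.event_match_mode not in ("exact", "substring"):
            raise CaseConfigError(
                f"unknown event_match_mode {self.event_match_mode!r}")
        self.synonym_index()  # raises on ambiguity

    def synonym_index(self) -> dict[str, str]:
        """Normalised synonym -> drug_id; ambiguity is a configuration error."""
        index: dict[str, str] = {}
        for drug_id, synonyms in self.drug_dictionary.items():
            for syn in set(synonyms) | {drug_id}:
                norm = normalize_name(syn)
                if not norm:
                    continue
                if index.get(norm, drug_id) != drug_id:
                    raise CaseConfigError(
                        f"synonym {norm!r} claimed by both "
                        f"{index[norm]!r} and {drug_id!r}")
                index[norm] = drug_id
        return index

    def normalized_event_terms(self) -> set[str]:
        return {normalize_term(t) for t in self.event_terms}

    def normalized_indication_terms(self) -> set[str]:
        return {normalize_term(t) for t in self.indication_terms}

    @classmethod
    def from_yaml(cls, path) -> "CaseDefinition":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            drug_dictionary={k: set(v) for k, v in raw.get("drugs", {}).items()},
            event_terms=set(raw.get("event_terms", ())),
            allowed_roles=set(raw.get("allowed_roles", ("PS", "SS"))),
            indication_terms=set(raw.get("indication_terms", ())),
            match_mode=raw.get("match_mode", "exact"),
            event_match_mode=raw.get("event_match_mode", "exact"),
        )


def default_case_definition() -> CaseDefinition:
    """The bundled rheumatoid-arthritis biologics / heart-failure case
    definition (four target drugs, six cardiac-failure preferred terms)."""
    path = resources.files("pvdispro").joinpath("data/default_casedef.yaml")
    with resources.as_file(path) as p:
        return CaseDefinition.from_yaml(p)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _report_id_key(rid: str) -> str:
    # numeric ids compare numerically via zero-padding; mixed ids fall
    # back to a deterministic lexicographic order
    s = str(rid)
    return s.zfill(24) if s.isdigit() else "~" + s


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Collapse report versions: one row per ``case_id``, keeping the
    version with the latest receipt date.

    Ties on receipt date are broken by the greatest report identifier
    (report identifiers increase with resubmission).  Idempotent; empty
    input returns empty output.
    """
    if demo.empty:
        return demo.copy()
    key_date = demo["receipt_date"].map(date_sort_key)
    key_rid = demo["report_id"].map(_report_id_key)
    order = (demo.assign(_kd=key_date, _kr=key_rid)
             .sort_values(["case_id", "_kd", "_kr"], kind="mergesort"))
    kept = order.groupby("case_id", sort=False).tail(1)
    return (kept.drop(columns=["_kd", "_kr"])
            .sort_index().reset_index(drop=True))


# ---------------------------------------------------------------------------
# drug mapping and filters
# ---------------------------------------------------------------------------

def map_drug_records(drug: pd.DataFrame,
                     case_def: CaseDefinition) -> pd.DataFrame:
    """Record-level dictionary matches.

    Returns a frame with columns ``report_id, drug_seq, drug_id``: one
    row per drug record whose role is allowed and whose normalised
    verbatim name (or active ingredient) matches the dictionary.
    """
    index = case_def.synonym_index()
    eligible = drug[drug["role_code"].isin(case_def.allowed_roles)]
    if eligible.empty:
        return pd.DataFrame(columns=["report_id", "drug_seq", "drug_id"])
    rows = []
    names = eligible["verbatim_name"].map(normalize_name)
    ingredients = (eligible["active_ingredient"].map(normalize_name)
                   if "active_ingredient" in eligible.columns else None)
    if case_def.match_mode == "exact":
        for pos, (rid, seq) in enumerate(
                zip(eligible["report_id"], eligible["drug_seq"])):
            hit = index.get(names.iloc[pos])
            if hit is None and ingredients is not None:
                hit = index.get(ingredients.iloc[pos])
            if hit is not None:
                rows.append((rid, seq, hit))
    else:  # substring: any synonym contained in the normalised name
        for pos, (rid, seq) in enumerate(
                zip(eligible["report_id"], eligible["drug_seq"])):
            text = names.iloc[pos]
            if ingredients is not None:
                text = text + " | " + ingredients.iloc[pos]
            for syn, drug_id in index.items():
                if syn in text:
                    rows.append((rid, seq, drug_id))
    return (pd.DataFrame(rows, columns=["report_id", "drug_seq", "drug_id"])
            .drop_duplicates().reset_index(drop=True))


def map_drugs(drug: pd.DataFrame,
              case_def: CaseDefinition) -> dict[str, set[str]]:
    """``report_id -> set of matched drug_ids`` (suspect roles only)."""
    records = map_drug_records(drug, case_def)
    return {rid: set(grp["drug_id"])
            for rid, grp in records.groupby("report_id", sort=False)}


def apply_indication_filter(matches: pd.DataFrame, indi: pd.DataFrame,
                            case_def: CaseDefinition) -> pd.DataFrame:
    """Keep record-level matches whose drug record carries a qualifying
    indication.

    *matches* is the frame returned by :func:`map_drug_records`.  A
    (report, drug_seq) match survives iff some indication record for the
    same report and drug_seq normalises into ``indication_terms``.  An
    empty ``indication_terms`` disables the filter.
    """
    terms = case_def.normalized_indication_terms()
    if not terms or matches.empty:
        return matches
    qual = indi[indi["indication_term"].map(normalize_term).isin(terms)]
    keys = set(zip(qual["report_id"], qual["drug_seq"]))
    mask = [(rid, seq) in keys
            for rid, seq in zip(matches["report_id"], matches["drug_seq"])]
    return matches[mask].reset_index(drop=True)


def flag_events(reac: pd.DataFrame, case_def: CaseDefinition) -> set[str]:
    """Report ids with at least one reaction term matching the event list.

    Matching is term-level equality after normalisation by default;
    ``event_match_mode='substring'`` flags any reaction containing an
    event term as a substring (sensitivity-analysis mode).
    """
    terms = case_def.normalized_event_terms()
    norm = reac["preferred_term"].map(normalize_term)
    if case_def.event_match_mode == "exact":
        hit = norm.isin(terms)
    else:
        hit = norm.map(lambda s: any(t in s for t in terms))
    return set(reac.loc[hit, "report_id"])


# ---------------------------------------------------------------------------
# outcomes and demographics
# ---------------------------------------------------------------------------

def classify_outcome(codes) -> str:
    """Mutually exclusive severity class for a report's outcome codes.

    Most serious wins: death (DE) over disability (DS or congenital
    anomaly CA) over other-serious (LT, HO, RI, OT) over none, so a
    report is counted exactly once.
    """
    codes = set(codes)
    unknown = codes - set(OUTCOME_CODES)
    if unknown:
        raise ValueError(f"unknown outcome codes: {sorted(unknown)}")
    if "DE" in codes:
        return "death"
    if codes & {"DS", "CA"}:
        return "disability"
    if codes & {"LT", "HO", "RI", "OT"}:
        return "other-serious"
    return "none"


def age_to_years(age_value: float, age_unit: str) -> float:
    """Convert a FAERS age value/unit pair to years (NaN if unit unknown)."""
    if age_value is None or (isinstance(age_value, float) and math.isnan(age_value)):
        return math.nan
    if age_value < 0:
        raise ValueError(f"negative age value {age_value}")
    factor = AGE_UNIT_FACTORS.get(str(age_unit).upper())
    return math.nan if factor is None else age_value * factor


def age_band(years: float) -> str:
    if years is None or math.isnan(years):
        return "unknown"
    if years < 18:
        return "<18"
    if years < 45:
        return "18-44"
    if years < 65:
        return "45-64"
    if years < 75:
        return "65-74"
    if years < 85:
        return "75-84"
    return ">85"


_REGION_MAP: dict[str, str] | None = None


def _region_map() -> dict[str, str]:
    global _REGION_MAP
    if _REGION_MAP is None:
        path = resources.files("pvdispro").joinpath("data/country_regions.tsv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        m: dict[str, str] = {}
        for code, name, region in df.itertuples(index=False):
            m[code.upper()] = region
            m[name.upper()] = region
        _REGION_MAP = m
    return _REGION_MAP


def country_to_region(country: str) -> str:
    """Map a country code or name to one of six continents, else unknown."""
    return _region_map().get(str(country).strip().upper(), "unknown")


def _reporter_class(code: str) -> str:
    c = str(code).strip().upper()
    if c in _HEALTH_PROFESSIONAL:
        return "health-professional"
    if c in _CONSUMER:
        return "consumer"
    return "unknown"


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_cases(bundle: FaersBundle, case_def: CaseDefinition,
                   keep: str = "all") -> pd.DataFrame:
    """Compose the full pipeline into one analysis table.

    Steps: deduplicate -> restrict child tables to kept versions ->
    drug dictionary matching -> indication filter -> event flag ->
    outcome classification -> demographics normalisation.

    Parameters
    ----------
    keep
        ``all``   one row per deduplicated report (full background, as
                  the disproportionality statistics require);
        ``drug``  only reports with >=1 qualifying target drug;
        ``drug_and_event``  only target-drug reports with the event of
                  interest (the descriptive case series).
    """
    if keep not in ("all", "drug", "drug_and_event"):
        raise ValueError(f"unknown keep mode {keep!r}")
    demo = deduplicate(bundle.demo)
    kept_ids = set(demo["report_id"])

    drug = bundle.drug[bundle.drug["report_id"].isin(kept_ids)]
    reac = bundle.reac[bundle.reac["report_id"].isin(kept_ids)]
    outc = bundle.outc[bundle.outc["report_id"].isin(kept_ids)]
    indi = bundle.indi[bundle.indi["report_id"].isin(kept_ids)]

    matches = map_drug_records(drug, case_def)
    matches = apply_indication_filter(matches, indi, case_def)
    drug_sets = {rid: frozenset(grp["drug_id"])
                 for rid, grp in matches.groupby("report_id", sort=False)}
    event_ids = flag_events(reac, case_def)
    code_sets = {rid: frozenset(grp["outcome_code"])
                 for rid, grp in outc.groupby("report_id", sort=False)}

    age_years = [age_to_years(v, u) for v, u in
                 zip(demo["age_value"], demo["age_unit"])]
    sex = demo["sex"].map(lambda s: s if s in ("M", "F") else "unknown")

    out = pd.DataFrame({
        "report_id": demo["report_id"].to_numpy(),
        "case_id": demo["case_id"].to_numpy(),
        "suspect_drug_ids": [tuple(sorted(drug_sets.get(r, ())))
                             for r in demo["report_id"]],
        "has_target_event": [r in event_ids for r in demo["report_id"]],
        "outcome_codes": [tuple(sorted(code_sets.get(r, ())))
                          for r in demo["report_id"]],
        "outcome_class": [classify_outcome(code_sets.get(r, ()))
                          for r in demo["report_id"]],
        "receipt_year": demo["receipt_date"].map(
            lambda s: int(date_sort_key(s)[:4])),
        "sex": sex.to_numpy(),
        "age_years": age_years,
        "age_band": [age_band(a) for a in age_years],
        "region": demo["country"].map(country_to_region).to_numpy(),
        "reporter_type": demo["reporter_type"].map(_reporter_class).to_numpy(),
    })
    if keep == "drug":
        out = out[out["suspect_drug_ids"].map(bool)]
    elif keep == "drug_and_event":
        out = out[out["suspect_drug_ids"].map(bool) & out["has_target_event"]]
    return out.reset_index(drop=True)


def write_cases(cases: pd.DataFrame, path: str | Path) -> Path:
    """Serialise a case table to TSV (tuple columns joined with ';')."""
    df = cases.copy()
    for col in ("suspect_drug_ids", "outcome_codes"):
        df[col] = df[col].map(";".join)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cases(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"report_id": str, "case_id": str},
                     keep_default_na=False)
    for col in ("suspect_drug_ids", "outcome_codes"):
        df[col] = df[col].map(lambda s: tuple(s.split(";")) if s else ())
    df["has_target_event"] = df["has_target_event"].map(
        {"True": True, "False": False, True: True, False: False})
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    return df
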