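"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS quarterly data are distributed as '$'-delimited text files with a
single header row, one file per table: demographics (DEMO), drugs (DRUG),
reactions (REAC), outcomes (OUTC), therapy dates (THER) and indications
(INDI).  Two header dialects exist: the *current* one keyed by
``primaryid``/``caseid`` and the pre-2012Q4 *legacy* one keyed by
``isr``/``case``.  Both are normalised here into one internal schema so
the rest of the pipeline never sees dialect differences.

Internal schema column names (all tables carry ``report_id``):

========  =====================================================
table     columns
========  =====================================================
demo      report_id, case_id, receipt_date, event_date, sex,
          age_value, age_unit, country, reporter_type
drug      report_id, drug_seq, role_code, verbatim_name,
          active_ingredient
reac      report_id, preferred_term
outc      report_id, outcome_code
ther      report_id, drug_seq, start_date, end_date
indi      report_id, drug_seq, indication_term
========  =====================================================

Dates are kept as digit strings (``YYYYMMDD``; partial ``YYYY`` /
``YYYYMM`` accepted and flagged, never interpolated).  ``age_value`` is
float (NaN when missing); every other field is a string with ``""`` for
missing.  Unknown columns are preserved verbatim as opaque extras.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pvdispro")

DELIMITER = "$"
ESCAPECHAR = "\\"

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
AGE_UNITS = ("DEC", "YR", "MON", "WK", "DY", "HR")

TABLES = ("demo", "drug", "reac", "outc", "ther", "indi")

#: internal column order per table
SCHEMA: dict[str, list[str]] = {
    "demo": ["report_id", "case_id", "receipt_date", "event_date", "sex",
             "age_value", "age_unit", "country", "reporter_type"],
    "drug": ["report_id", "drug_seq", "role_code", "verbatim_name",
             "active_ingredient"],
    "reac": ["report_id", "preferred_term"],
    "outc": ["report_id", "outcome_code"],
    "ther": ["report_id", "drug_seq", "start_date", "end_date"],
    "indi": ["report_id", "drug_seq", "indication_term"],
}

#: on-disk header names (current FAERS dialect) per internal column
_CURRENT_NAMES: dict[str, dict[str, str]] = {
    "demo": {"report_id": "primaryid", "case_id": "caseid",
             "receipt_date": "fda_dt", "event_date": "event_dt",
             "sex": "sex", "age_value": "age", "age_unit": "age_cod",
             "country": "occr_country", "reporter_type": "occp_cod"},
    "drug": {"report_id": "primaryid", "drug_seq": "drug_seq",
             "role_code": "role_cod", "verbatim_name": "drugname",
             "active_ingredient": "prod_ai"},
    "reac": {"report_id": "primaryid", "preferred_term": "pt"},
    "outc": {"report_id": "primaryid", "outcome_code": "outc_cod"},
    "ther": {"report_id": "primaryid", "drug_seq": "dsg_drug_seq",
             "start_date": "start_dt", "end_date": "end_dt"},
    "indi": {"report_id": "primaryid", "drug_seq": "indi_drug_seq",
             "indication_term": "indi_pt"},
}

#: additional header aliases accepted on read (legacy dialect)
_ALIASES: dict[str, dict[str, str]] = {
    "demo": {"isr": "report_id", "case": "case_id", "gndr_cod": "sex",
             "reporter_country": "country"},
    "drug": {"isr": "report_id"},
    "reac": {"isr": "report_id"},
    "outc": {"isr": "report_id"},
    "ther": {"isr": "report_id", "drug_seq": "drug_seq"},
    "indi": {"isr": "report_id", "drug_seq": "drug_seq", "indi_pt": "indication_term"},
}


class FaersIOError(IOError):
    """A quarterly table file is missing or unreadable."""


class FaersParseError(ValueError):
    """Too many malformed rows in a quarterly table file."""


# ---------------------------------------------------------------------------
# bundle container
# ---------------------------------------------------------------------------

def _empty(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in SCHEMA[table]})
    return _coerce_dtypes(table, df)


def _coerce_dtypes(table: str, df: pd.DataFrame) -> pd.DataFrame:
    """Fix the dtypes of the schema columns: strings everywhere except
    float ``age_value`` and integer ``drug_seq``."""
    df = df.copy()
    for col in SCHEMA[table]:
        if col not in df.columns:
            df[col] = np.nan if col == "age_value" else ""
        if col == "age_value":
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        elif col == "drug_seq":
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(np.int64)
        else:
            df[col] = df[col].fillna("").astype(str)
    extras = [c for c in df.columns if c not in SCHEMA[table]]
    return df[SCHEMA[table] + extras].reset_index(drop=True)


@dataclass
class FaersBundle:
    """The six linked report tables of one FAERS-style dataset.

    Child tables link to ``demo`` through ``report_id``.
    """

    demo: pd.DataFrame = field(default_factory=lambda: _empty("demo"))
    drug: pd.DataFrame = field(default_factory=lambda: _empty("drug"))
    reac: pd.DataFrame = field(default_factory=lambda: _empty("reac"))
    outc: pd.DataFrame = field(default_factory=lambda: _empty("outc"))
    ther: pd.DataFrame = field(default_factory=lambda: _empty("ther"))
    indi: pd.DataFrame = field(default_factory=lambda: _empty("indi"))

    def __post_init__(self) -> None:
        for t in TABLES:
            setattr(self, t, _coerce_dtypes(t, getattr(self, t)))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {t: getattr(self, t) for t in TABLES}

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def validate(self) -> None:
        """Raise ``ValueError`` on referential-integrity violations."""
        known = set(self.demo["report_id"])
        if len(known) != len(self.demo):
            raise ValueError("duplicate report_id in demo table")
        for t in TABLES[1:]:
            ids = set(getattr(self, t)["report_id"])
            orphans = ids - known
            if orphans:
                raise ValueError(
                    f"{t} table has {len(orphans)} report_id values absent "
                    f"from demo (e.g. {sorted(orphans)[:3]})")

    def equals(self, other: "FaersBundle") -> bool:
        return all(getattr(self, t).equals(getattr(other, t)) for t in TABLES)


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

def date_sort_key(date_str: str) -> str:
    """Sortable 8-digit key for a possibly partial FAERS date.

    Missing month/day components compare as earliest (padded with the
    lowest valid value), so ``"2019"`` sorts before ``"20190102"``.
    Empty or non-digit strings sort before everything.
    """
    s = str(date_str).strip()
    if not s.isdigit():
        return "00000000"
    if len(s) == 4:
        return s + "0101"
    if len(s) == 6:
        return s + "01"
    if len(s) == 8:
        return s
    return "00000000"


def is_partial_date(date_str: str) -> bool:
    s = str(date_str).strip()
    return s.isdigit() and len(s) in (4, 6)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _find_table_file(directory: Path, table: str) -> Path:
    """Locate e.g. DEMO20Q3.txt / demo.txt in *directory* (prefix match)."""
    cand = sorted(p for p in directory.iterdir()
                  if p.is_file() and p.name.lower().startswith(table))
    if not cand:
        raise FaersIOError(f"no {table.upper()} file found in {directory}")
    if len(cand) > 1:
        logger.warning("multiple %s files in %s; using %s",
                       table.upper(), directory, cand[0].name)
    return cand[0]


def _read_delimited(path: Path, tolerance: float) -> tuple[pd.DataFrame, int]:
    """Read one '$'-delimited file; returns (frame, n_malformed)."""
    raw = path.read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("utf-8", errors="replace")
        logger.warning("%s: undecodable bytes replaced", path.name)
    bad: list[int] = []

    def _on_bad(row: list[str]) -> None:
        bad.append(len(bad))
        return None

    df = pd.read_csv(
        _io.StringIO(text), sep=DELIMITER, engine="python",
        quoting=csv.QUOTE_NONE, escapechar=ESCAPECHAR,
        dtype=str, keep_default_na=False, on_bad_lines=_on_bad)
    n_rows = len(df) + len(bad)
    if bad and n_rows and len(bad) / n_rows > tolerance:
        raise FaersParseError(
            f"{path.name}: {len(bad)}/{n_rows} malformed rows exceeds "
            f"tolerance {tolerance}")
    if bad:
        logger.warning("%s: dropped %d malformed rows", path.name, len(bad))
    return df, len(bad)


def detect_dialect(columns: list[str]) -> str:
    """``legacy`` if the header exposes ISR/CASE identifiers, else ``current``."""
    lower = {c.lower() for c in columns}
    return "legacy" if "isr" in lower else "current"


def _normalise_columns(table: str, df: pd.DataFrame) -> pd.DataFrame:
    rename: dict[str, str] = {}
    current_inv = {v: k for k, v in _CURRENT_NAMES[table].items()}
    for col in df.columns:
        key = col.lower().strip()
        if key in current_inv:
            rename[col] = current_inv[key]
        elif key in _ALIASES[table]:
            rename[col] = _ALIASES[table][key]
    df = df.rename(columns=rename)
    # upper-case the controlled vocabularies
    for col in ("role_code", "outcome_code", "age_unit", "sex"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip().str.upper()
    return _coerce_dtypes(table, df)


def read_quarter(directory: str | Path, dialect: str = "auto",
                 tolerance: float = 0.05) -> FaersBundle:
    """Read one quarterly directory of six '$'-delimited tables.

    Parameters
    ----------
    directory
        Directory containing DEMO*/DRUG*/REAC*/OUTC*/THER*/INDI* files.
    dialect
        ``current``, ``legacy`` or ``auto`` (header inspection per file).
    tolerance
        Maximum tolerated fraction of malformed rows per file before a
        :class:`FaersParseError` is raised; malformed rows below the
        tolerance are counted and logged, never silently dropped.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FaersIOError(f"not a directory: {directory}")
    if dialect not in ("current", "legacy", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frames: dict[str, pd.DataFrame] = {}
    for table in TABLES:
        path = _find_table_file(directory, table)
        df, _ = _read_delimited(path, tolerance)
        found = detect_dialect(list(df.columns))
        if dialect != "auto" and found != dialect:
            logger.warning("%s: header looks %s but dialect=%s requested",
                           path.name, found, dialect)
        frames[table] = _normalise_columns(table, df)
    bundle = FaersBundle(**frames)
    bundle.validate()
    n_partial = int(bundle.demo["receipt_date"].map(is_partial_date).sum())
    if n_partial:
        logger.warning("demo: %d partial receipt dates", n_partial)
    return bundle


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_age(v: float) -> str:
    if pd.isna(v):
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_quarter(bundle: FaersBundle, directory: str | Path) -> Path:
    """Write *bundle* as six '$'-delimited files (current-dialect headers).

    Literal ``$`` and backslash characters inside values are escaped with
    a backslash so that :func:`read_quarter` round-trips field-for-field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table in TABLES:
        df = getattr(bundle, table).copy()
        if "age_value" in df.columns:
            df["age_value"] = df["age_value"].map(_format_age)
        if "drug_seq" in df.columns:
            df["drug_seq"] = df["drug_seq"].astype(str)
        extras = [c for c in df.columns if c not in SCHEMA[table]]
        df = df[SCHEMA[table] + extras]
        df = df.rename(columns=_CURRENT_NAMES[table])
        out = directory / f"{table.upper()}.txt"
        df.to_csv(out, sep=DELIMITER, index=False, quoting=csv.QUOTE_NONE,
                  escapechar=ESCAPECHAR, lineterminator="\n")
    return directory
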