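"""Descriptive outputs and the end-to-end pipeline driver.

Produces the characteristics summary (per-drug counts, region, reporter,
sex, age band, outcomes), per-drug reports-per-year trend tables and
per-drug outcome-class proportions, and orchestrates
ingest -> cases -> signals -> summaries from one call.
"""

from __future__ import annotations

import hashlib
import json
import logging
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import cases as _cases
from . import stats as _stats
from .cases import CaseDefinition, assemble_cases, AGE_BANDS, REGIONS
from .io import FaersBundle, OUTCOME_CODES, read_quarter

logger = logging.getLogger("pvdispro")

__all__ = ["percent", "summarize_cases", "trend_by_year",
           "outcome_proportions", "run_pipeline"]

OUTCOME_CODE_LABELS = {
    "DE": "Death", "DS": "Disability", "CA": "Congenital anomaly",
    "HO": "Hospitalization", "LT": "Life-threatening",
    "RI": "Required intervention", "OT": "Other serious",
}
OUTCOME_CLASSES = ("death", "disability", "other-serious", "none")


def percent(count: int, total: int) -> float:
    """Share of *total* as a percentage, rounded half-up to 2 decimals.

    Decimal arithmetic, so 53.835 rounds to 53.84 (not banker's
    rounding).
    """
    if total == 0:
        raise ValueError("total must be positive")
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _section(rows: list, section: str, labels, counts: dict[str, int],
             total: int) -> None:
    for label in labels:
        n = counts.get(label, 0)
        rows.append((section, label, n, percent(n, total)))


def summarize_cases(cases: pd.DataFrame) -> pd.DataFrame:
    """Characteristics summary of a case series.

    One row per (section, label) with count and percent of the grand
    total.  Sections: suspect drug, reporting region, reporter, sex,
    age band, outcome codes (non-exclusive: a report can contribute to
    several rows) and outcome classes (mutually exclusive).  Within
    every exhaustive section (region, reporter, sex, age band, outcome
    class) counts sum to the grand total.
    """
    if cases.empty:
        raise ValueError("cases table is empty")
    total = len(cases)
    rows: list = [("total", "Total reports", total, percent(total, total))]

    drug_counts: dict[str, int] = {}
    for ids in cases["suspect_drug_ids"]:
        for d in ids:
            drug_counts[d] = drug_counts.get(d, 0) + 1
    _section(rows, "suspect drug", sorted(drug_counts), drug_counts, total)

    _section(rows, "reporting region", REGIONS,
             cases["region"].value_counts().to_dict(), total)
    _section(rows, "reporter",
             ("health-professional", "consumer", "unknown"),
             cases["reporter_type"].value_counts().to_dict(), total)
    _section(rows, "sex", ("M", "F", "unknown"),
             cases["sex"].value_counts().to_dict(), total)
    _section(rows, "age band", AGE_BANDS,
             cases["age_band"].value_counts().to_dict(), total)

    code_counts = {code: int(cases["outcome_codes"]
                             .map(lambda cs: code in cs).sum())
                   for code in OUTCOME_CODES}
    for code in OUTCOME_CODES:
        rows.append(("outcome code (non-exclusive)",
                     OUTCOME_CODE_LABELS[code], code_counts[code],
                     percent(code_counts[code], total)))
    _section(rows, "outcome class (exclusive)", OUTCOME_CLASSES,
             cases["outcome_class"].value_counts().to_dict(), total)

    return pd.DataFrame(rows, columns=["section", "label", "count", "percent"])


def trend_by_year(cases: pd.DataFrame,
                  years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Report counts per (drug, receipt year), zero-filled over the
    complete grid.

    *years* is the inclusive window; by default the span observed in
    the data.  A report naming several target drugs counts once for
    each.
    """
    if cases.empty:
        raise ValueError("cases table is empty")
    if years is None:
        years = (int(cases["receipt_year"].min()),
                 int(cases["receipt_year"].max()))
    lo, hi = years
    exploded = (cases[["receipt_year", "suspect_drug_ids"]]
                .explode("suspect_drug_ids")
                .dropna(subset=["suspect_drug_ids"]))
    exploded = exploded[(exploded["receipt_year"] >= lo)
                        & (exploded["receipt_year"] <= hi)]
    drugs = sorted(set(d for ids in cases["suspect_drug_ids"] for d in ids))
    counts = (exploded.groupby(["suspect_drug_ids", "receipt_year"])
              .size().to_dict())
    rows = [(d, y, counts.get((d, y), 0))
            for d in drugs for y in range(lo, hi + 1)]
    return pd.DataFrame(rows, columns=["drug_id", "year", "count"])


def outcome_proportions(cases: pd.DataFrame) -> pd.DataFrame:
    """Per-drug outcome-class percentages (of that drug's case total).

    Every class row is present (0.00 when empty); per drug the four
    class percentages sum to 100 within rounding.
    """
    if cases.empty:
        raise ValueError("cases table is empty")
    exploded = (cases[["suspect_drug_ids", "outcome_class"]]
                .explode("suspect_drug_ids")
                .dropna(subset=["suspect_drug_ids"]))
    rows = []
    for drug_id, grp in exploded.groupby("suspect_drug_ids"):
        total = len(grp)
        counts = grp["outcome_class"].value_counts().to_dict()
        for cls in OUTCOME_CLASSES:
            n = counts.get(cls, 0)
            rows.append((drug_id, cls, n, percent(n, total)))
    return pd.DataFrame(rows, columns=["drug_id", "outcome_class",
                                       "count", "percent"])


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(bundle: FaersBundle | str | Path,
                 case_def: CaseDefinition | str | Path,
                 out_dir: str | Path,
                 criteria: _stats.SignalCriteria = _stats.SignalCriteria(),
                 correction: str = "none",
                 ic_mode: str = "normal") -> dict:
    """Run ingest -> cases -> signals -> summaries and write TSVs.

    Writes ``signals.tsv``, ``summary.tsv``, ``trends.tsv``,
    ``outcomes.tsv`` and ``manifest.json`` (config hashes plus row
    counts at every filter stage) into *out_dir*.  Returns the frames
    and the manifest as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stage_counts": {}}

    if not isinstance(bundle, FaersBundle):
        manifest["bundle_path"] = str(bundle)
        bundle = read_quarter(bundle)
    if not isinstance(case_def, CaseDefinition):
        manifest["casedef_hash"] = _sha256_file(Path(case_def))
        case_def = CaseDefinition.from_yaml(case_def)

    counts = manifest["stage_counts"]
    counts["screened_report_versions"] = int(len(bundle.demo))

    background = assemble_cases(bundle, case_def, keep="all")
    counts["deduplicated_reports"] = int(len(background))
    case_series = background[background["suspect_drug_ids"].map(bool)]
    counts["target_drug_reports"] = int(len(case_series))
    case_series = case_series[case_series["has_target_event"]]
    counts["retained_cases"] = int(len(case_series))
    if not (counts["screened_report_versions"]
            >= counts["deduplicated_reports"]
            >= counts["target_drug_reports"]
            >= counts["retained_cases"]):
        raise AssertionError("filter-stage counts must be non-increasing")
    logger.info("pipeline stages: %s", counts)

    drug_ids = sorted(case_def.drug_dictionary)
    signals = _stats.screen_all_pairs(background, drug_ids,
                                      criteria=criteria,
                                      correction=correction, ic_mode=ic_mode)
    result = {"signals": signals, "manifest": manifest,
              "background": background, "cases": case_series}
    signals.to_csv(out_dir / "signals.tsv", sep="\t", index=False)

    if len(case_series):
        summary = summarize_cases(case_series)
        trends = trend_by_year(case_series)
        outcomes = outcome_proportions(case_series)
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        trends.to_csv(out_dir / "trends.tsv", sep="\t", index=False)
        outcomes.to_csv(out_dir / "outcomes.tsv", sep="\t", index=False)
        result.update(summary=summary, trends=trends, outcomes=outcomes)
    else:
        logger.warning("no retained cases; descriptive tables skipped")

    _cases.write_cases(case_series, out_dir / "cases.tsv")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def plot_trends(trends: pd.DataFrame, path: str | Path) -> Path:
    """Optional convenience line chart of the trend table (requires
    matplotlib); the TSVs are the contract, images are derived."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for drug_id, grp in trends.groupby("drug_id"):
        ax.plot(grp["year"], grp["count"], marker="o", label=drug_id)
    ax.set_xlabel("receipt year")
    ax.set_ylabel("reports")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
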