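"""Disproportionality statistics on 2x2 contingency tables.

The case/non-case method compares reporting of an event of interest
between reports that carry the drug of interest (as a suspect drug) and
all other reports:

====================  ==============  ===================
                      drug of         all other drugs
                      interest
====================  ==============  ===================
event of interest     a               b
all other events      c               d
====================  ==============  ===================

Four classical signal-detection statistics are computed with their
conventional criteria:

* ROR, reporting odds ratio ``ad/(bc)``; 95% CI
  ``exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d))``;
  signal when the CI lower bound > 1 and N >= 2.
* PRR ``[a/(a+c)] / [b/(b+d)]`` with the four-cell Pearson chi-square;
  signal when PRR >= 2, chi2 >= 4 and N >= 3.
* BCPNN information component ``IC = log2[a n / ((a+b)(a+c))]``;
  signal when its lower 95% bound IC025 > 0.
* Simplified MGPS ``EBGM = a n / ((a+b)(a+c))`` (the unshrunken
  observed/expected ratio — see note below) with one-sided lower bound
  ``EBGM05 = exp(ln EBGM - 1.64 sqrt(1/a+1/b+1/c+1/d))``;
  signal when EBGM05 > 2 and N > 0.

N is the case count ``a``.  In these simplified forms IC and EBGM are
the same quantity on different scales, ``IC = log2(EBGM)`` exactly.

.. note::
   A full MGPS fits a two-component gamma-Poisson mixture by empirical
   Bayes and shrinks small-count cells toward 1.  The EBGM here is the
   raw observed/expected ratio with a normal-approximation bound: for
   small ``a`` it will exceed (and its bound will be wider than) a true
   shrunken MGPS estimate.  Treat small-count EBGM values accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["ContingencyTable", "SignalCriteria", "SignalResult",
           "build_contingency", "ror", "prr_chi2", "bcpnn_ic", "mgps_ebgm",
           "compute_signal", "evaluate_criteria", "screen_all_pairs"]

Z_95_TWO_SIDED = 1.96
Z_95_ONE_SIDED = 1.64


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the drug x event 2x2 table (counts, or corrected floats)."""
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self, k: float = 0.5) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction: add *k* to all cells."""
        return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def build_contingency(cases: pd.DataFrame, drug_id: str,
                      event_flag=None) -> ContingencyTable:
    """Count the 2x2 cells from a case table spanning the full background.

    ``cases`` must contain every deduplicated report (all drugs, all
    events), with ``suspect_drug_ids`` tuples and either a boolean
    ``has_target_event`` column or an explicit *event_flag* (boolean
    array aligned with ``cases``, or a set of report ids).
    """
    if cases.empty:
        raise ValueError("cases table is empty")
    exposed = cases["suspect_drug_ids"].map(lambda ids: drug_id in ids).to_numpy()
    if event_flag is None:
        event = cases["has_target_event"].to_numpy(dtype=bool)
    elif isinstance(event_flag, (set, frozenset)):
        event = cases["report_id"].isin(event_flag).to_numpy()
    else:
        event = np.asarray(event_flag, dtype=bool)
        if event.shape[0] != len(cases):
            raise ValueError("event_flag length mismatch")
    a = int(np.sum(exposed & event))
    b = int(np.sum(~exposed & event))
    c = int(np.sum(exposed & ~event))
    d = int(np.sum(~exposed & ~event))
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def _se_log(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def _apply_correction(t: ContingencyTable, correction: str) -> ContingencyTable:
    if correction == "haldane" and t.has_zero_cell:
        return t.corrected(0.5)
    return t


def ror(t: ContingencyTable, correction: str = "none") -> RorResult:
    """Reporting odds ratio with two-sided 95% CI.

    A zero cell with ``correction='none'`` yields NaN (flagged
    undefined, never an exception); ``correction='haldane'`` adds 0.5 to
    every cell of tables with a zero cell first.
    """
    t = _apply_correction(t, correction)
    if t.has_zero_cell:
        return RorResult(math.nan, math.nan, math.nan)
    estimate = (t.a * t.d) / (t.b * t.c)
    half = Z_95_TWO_SIDED * _se_log(t)
    return RorResult(estimate, estimate * math.exp(-half),
                     estimate * math.exp(half))


def prr_chi2(t: ContingencyTable, yates: bool = False) -> PrrResult:
    """Proportional reporting ratio and the four-cell Pearson chi-square.

    ``chi2 = sum (O-E)^2 / E`` over the four cells with expectations from
    the margins; no continuity correction unless *yates*.  Zero margins
    yield NaN for the affected statistic.
    """
    drug_total = t.a + t.c
    other_total = t.b + t.d
    if drug_total == 0 or other_total == 0 or t.b == 0:
        prr = math.nan
    else:
        prr = (t.a / drug_total) / (t.b / other_total)
    event_total = t.a + t.b
    nonevent_total = t.c + t.d
    if 0 in (drug_total, other_total, event_total, nonevent_total):
        return PrrResult(prr, math.nan)
    chi2 = 0.0
    for obs, row, col in ((t.a, event_total, drug_total),
                          (t.b, event_total, other_total),
                          (t.c, nonevent_total, drug_total),
                          (t.d, nonevent_total, other_total)):
        expected = row * col / t.n
        dev = abs(obs - expected)
        if yates:
            dev = max(0.0, dev - 0.5)
        chi2 += dev * dev / expected
    return PrrResult(prr, chi2)


def bcpnn_ic(t: ContingencyTable, correction: str = "none",
             mode: str = "normal") -> IcResult:
    """BCPNN information component ``IC = log2[a n / ((a+b)(a+c))]``.

    ``mode='normal'`` (default) puts the 95% lower bound on the log2
    scale: ``IC025 = IC - (1.96/ln 2) sqrt(1/a+1/b+1/c+1/d)``, defined
    for any IC.  ``mode='multiplicative'`` is the alternative form
    ``IC * exp(-1.96 sqrt(...))``, defined only for IC > 0 (NaN
    otherwise).
    """
    if mode not in ("normal", "multiplicative"):
        raise ValueError(f"unknown IC mode {mode!r}")
    t = _apply_correction(t, correction)
    if t.has_zero_cell:
        return IcResult(math.nan, math.nan)
    ic = math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c)))
    se = _se_log(t)
    if mode == "normal":
        ic025 = ic - (Z_95_TWO_SIDED / math.log(2)) * se
    else:
        ic025 = ic * math.exp(-Z_95_TWO_SIDED * se) if ic > 0 else math.nan
    return IcResult(ic, ic025)


def mgps_ebgm(t: ContingencyTable, correction: str = "none") -> EbgmResult:
    """Simplified (unshrunken) EBGM — the observed/expected reporting
    ratio ``a n / ((a+b)(a+c))`` — with its one-sided 95% lower bound
    ``EBGM05 = exp(ln EBGM - 1.64 sqrt(1/a+1/b+1/c+1/d))``."""
    t = _apply_correction(t, correction)
    if t.has_zero_cell:
        return EbgmResult(math.nan, math.nan)
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    ebgm05 = ebgm * math.exp(-Z_95_ONE_SIDED * _se_log(t))
    return EbgmResult(ebgm, ebgm05)


# ---------------------------------------------------------------------------
# criteria and batch screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalCriteria:
    """Signal thresholds, strict/inclusive exactly as conventionally
    printed: ROR CI lower bound > 1 with N >= 2; PRR >= 2 with
    chi2 >= 4 and N >= 3; IC025 > 0; EBGM05 > 2 with N > 0."""
    ror_ci_low: float = 1.0
    ror_min_n: int = 2
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_n: int = 3
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    mgps_min_n: int = 0

    def __post_init__(self) -> None:
        if min(self.ror_ci_low, self.prr_min, self.chi2_min,
               self.ebgm05_min) <= 0:
            raise ValueError("criteria thresholds must be positive")


@dataclass
class SignalResult:
    """All four statistics, bounds and per-algorithm flags for one pair."""
    drug_id: str
    n_reports: int  # = a, the case count
    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: dict[str, bool] = field(default_factory=dict)


def evaluate_criteria(result: SignalResult,
                      criteria: SignalCriteria = SignalCriteria()) -> dict[str, bool]:
    """Four independent truth values; undefined (NaN) statistics are
    never signals."""

    def ok(x: float) -> bool:
        return isinstance(x, (int, float)) and not math.isnan(x)

    n = result.n_reports
    return {
        "ror_signal": (ok(result.ror_ci_low)
                       and result.ror_ci_low > criteria.ror_ci_low
                       and n >= criteria.ror_min_n),
        "prr_signal": (ok(result.prr) and ok(result.chi2)
                       and result.prr >= criteria.prr_min
                       and result.chi2 >= criteria.chi2_min
                       and n >= criteria.prr_min_n),
        "bcpnn_signal": ok(result.ic025) and result.ic025 > criteria.ic025_min,
        "mgps_signal": (ok(result.ebgm05)
                        and result.ebgm05 > criteria.ebgm05_min
                        and n > criteria.mgps_min_n),
    }


def compute_signal(t: ContingencyTable, drug_id: str = "",
                   criteria: SignalCriteria = SignalCriteria(),
                   correction: str = "none",
                   ic_mode: str = "normal") -> SignalResult:
    """Compute every statistic and evaluate the signal criteria."""
    r = ror(t, correction)
    p = prr_chi2(t)
    i = bcpnn_ic(t, correction, ic_mode)
    e = mgps_ebgm(t, correction)
    result = SignalResult(
        drug_id=drug_id, n_reports=int(round(t.a)), table=t,
        ror=r.ror, ror_ci_low=r.ci_low, ror_ci_high=r.ci_high,
        prr=p.prr, chi2=p.chi2, ic=i.ic, ic025=i.ic025,
        ebgm=e.ebgm, ebgm05=e.ebgm05)
    result.flags = evaluate_criteria(result, criteria)
    return result


def screen_all_pairs(cases: pd.DataFrame, drug_ids, event_flag=None,
                     criteria: SignalCriteria = SignalCriteria(),
                     correction: str = "none",
                     ic_mode: str = "normal") -> pd.DataFrame:
    """One :class:`SignalResult` row per drug, all against the same
    background case table."""
    drug_ids = list(drug_ids)
    if not drug_ids:
        raise ValueError("need at least one drug_id")
    rows = []
    for drug_id in drug_ids:
        t = build_contingency(cases, drug_id, event_flag)
        s = compute_signal(t, drug_id, criteria, correction, ic_mode)
        rows.append({
            "drug_id": drug_id, "n": s.n_reports,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": s.ror, "ror_ci_low": s.ror_ci_low,
            "ror_ci_high": s.ror_ci_high,
            "prr": s.prr, "chi2": s.chi2,
            "ic": s.ic, "ic025": s.ic025,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            **s.flags,
        })
    return pd.DataFrame(rows)
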