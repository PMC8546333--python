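"""Study-condition validation experiments on the synthetic generator.

Two statistical contracts tie the generator to the signal statistics:

* **Null calibration** — with every true relative reporting ratio at 1,
  the ROR signal criterion (95% CI lower bound > 1, N >= 2) is a
  one-sided ~2.5% test, so the flag rate over many independent
  drug–event pairs must stay near that nominal level.
* **Relative-ratio recovery** — an injected association must be
  recovered: the ROR point estimate near the injected ratio, and the
  injected pair (and only it) flagged by all four criteria.

Both are exposed as plain functions so the test suite and the
acceptance script exercise identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cases import CaseDefinition, assemble_cases, flag_events, normalize_term
from .stats import SignalCriteria, build_contingency, compute_signal
from .synthetic import DrugSpec, EventSpec, GeneratorConfig, default_config, generate_bundle

__all__ = ["null_flag_rate", "recovery_experiment", "RecoveryResult",
           "single_event_case_definition"]


def single_event_case_definition(config: GeneratorConfig,
                                 event_term: str) -> CaseDefinition:
    """Case definition targeting one generated event term, with the
    generator's own drug synonyms as the dictionary."""
    return CaseDefinition(
        drug_dictionary={d.drug_id: set(d.synonyms) for d in config.drugs},
        event_terms={event_term},
        indication_terms=set())  # generator indications are uniform; filter off


def _null_config(n_reports: int, n_drugs: int, n_events: int,
                 p_drug: float, p_event: float, seed: int) -> GeneratorConfig:
    drugs = [DrugSpec(f"drug{i:02d}", (f"drug{i:02d}",), p_drug)
             for i in range(n_drugs)]
    events = [EventSpec(f"event {i:02d}", p_event) for i in range(n_events)]
    return GeneratorConfig(n_reports=n_reports, drugs=drugs, events=events,
                           associations={}, duplicate_rate=0.1, seed=seed)


def null_flag_rate(n_pairs: int = 2000, n_reports: int = 20_000,
                   pairs_per_bundle: int = 100, p_drug: float = 0.08,
                   p_event: float = 0.015, seed: int = 0,
                   criteria: SignalCriteria = SignalCriteria()) -> float:
    """Fraction of truly null drug–event pairs flagged by the ROR
    criterion.

    Pairs are laid out as sqrt-grid bundles (10 drugs x 10 events per
    bundle by default) with every relative reporting ratio at 1; each
    bundle runs through the full pipeline (dedup, dictionary match,
    event flag, 2x2 table, ROR CI).
    """
    grid = int(round(np.sqrt(pairs_per_bundle)))
    n_bundles = int(np.ceil(n_pairs / (grid * grid)))
    flagged = 0
    tested = 0
    for b in range(n_bundles):
        config = _null_config(n_reports, grid, grid, p_drug, p_event,
                              seed=seed + 7919 * b)
        bundle = generate_bundle(config)
        case_def = single_event_case_definition(config,
                                                config.events[0].term)
        cases = assemble_cases(bundle, case_def, keep="all")
        for event in config.events:
            term_def = single_event_case_definition(config, event.term)
            mask = cases["report_id"].isin(
                flag_events(bundle.reac, term_def)).to_numpy()
            for drug in config.drugs:
                if tested >= n_pairs:
                    break
                t = build_contingency(cases, drug.drug_id, mask)
                s = compute_signal(t, drug.drug_id, criteria)
                flagged += bool(s.flags["ror_signal"])
                tested += 1
    return flagged / tested


@dataclass
class RecoveryResult:
    """Per-replicate injected-pair estimates and flags."""
    table: pd.DataFrame  # seed, ror, all columns of the injected pair
    other_all_four: int  # replicates where any null drug hit all four criteria

    @property
    def rors(self) -> np.ndarray:
        return self.table["ror"].to_numpy()

    def fraction_in_band(self, low: float = 2.5, high: float = 3.5) -> float:
        r = self.rors
        return float(np.mean((r >= low) & (r <= high)))

    @property
    def fraction_all_four(self) -> float:
        return float(self.table["all_four"].mean())


def recovery_experiment(n_reports: int = 50_000, rr: float = 3.0,
                        n_replicates: int = 20, seed: int = 0) -> RecoveryResult:
    """Inject one association at ratio *rr* among four drugs and rerun
    the full pipeline across seeded replicates.

    The case definition targets the injected event term alone (the
    drug–event *pair* is what the ratio was injected into).  Returns
    per-replicate ROR estimates and criterion flags for the injected
    pair, plus how often any null drug satisfied all four criteria
    simultaneously (expected: never).
    """
    rows = []
    other_all_four = 0
    for i in range(n_replicates):
        config = default_config(n_reports=n_reports, seed=seed + 104729 * i,
                                rr=rr)
        (injected_drug, injected_event), = config.associations.keys()
        bundle = generate_bundle(config)
        case_def = single_event_case_definition(config, injected_event)
        cases = assemble_cases(bundle, case_def, keep="all")
        t = build_contingency(cases, injected_drug)
        s = compute_signal(t, injected_drug)
        rows.append({"seed": config.seed, "ror": s.ror,
                     "ror_ci_low": s.ror_ci_low, "prr": s.prr,
                     "chi2": s.chi2, "ic": s.ic, "ic025": s.ic025,
                     "ebgm": s.ebgm, "ebgm05": s.ebgm05,
                     **s.flags, "all_four": all(s.flags.values())})
        for drug in config.drugs:
            if drug.drug_id == injected_drug:
                continue
            so = compute_signal(build_contingency(cases, drug.drug_id),
                                drug.drug_id)
            if all(so.flags.values()):
                other_all_four += 1
    return RecoveryResult(table=pd.DataFrame(rows),
                          other_all_four=other_all_four)
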