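import pandas as pd
import pytest

import pvdispro as pv


@pytest.fixture(scope="session")
def small_config() -> pv.GeneratorConfig:
    return pv.default_config(n_reports=400, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> pv.FaersBundle:
    return pv.generate_bundle(small_config)


@pytest.fixture(scope="session")
def case_def() -> pv.CaseDefinition:
    return pv.default_case_definition()


def make_demo(rows):
    """Demo table from (report_id, case_id, receipt_date) triples."""
    return pd.DataFrame(
        [{"report_id": r, "case_id": c, "receipt_date": d} for r, c, d in rows])


def make_cases(rows):
    """Case table from (report_id, drug_ids, has_event) triples, with the
    remaining columns filled neutrally."""
    return pd.DataFrame([{
        "report_id": rid, "case_id": rid,
        "suspect_drug_ids": tuple(drugs), "has_target_event": event,
        "outcome_codes": (), "outcome_class": "none",
        "receipt_year": 2020, "sex": "unknown", "age_years": float("nan"),
        "age_band": "unknown", "region": "unknown",
        "reporter_type": "unknown"} for rid, drugs, event in rows])
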