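"""Case pipeline: deduplication, name normalisation, dictionary
matching, filters, outcome classification, demographics."""

import itertools
import math

import pandas as pd
import pytest

import pvdispro as pv
from pvdispro.cases import (AGE_BANDS, REGIONS, _region_map, age_band,
                            age_to_years, classify_outcome)

from conftest import make_demo


class TestDeduplicate:
    def test_keeps_latest_receipt_date(self):
        demo = make_demo([("1", "X", "20190101"), ("2", "X", "20200315")])
        kept = pv.deduplicate(demo)
        assert list(kept["report_id"]) == ["2"]

    def test_single_version_unchanged(self):
        demo = make_demo([("1", "X", "20190101")])
        pd.testing.assert_frame_equal(pv.deduplicate(demo), demo)

    def test_tie_breaks_on_greatest_report_id(self):
        demo = make_demo([("100", "X", "20200315"), ("101", "X", "20200315")])
        assert list(pv.deduplicate(demo)["report_id"]) == ["101"]
        # brute-force max over (date, numeric id) agrees
        best = max([("100", "20200315"), ("101", "20200315")],
                   key=lambda t: (t[1], int(t[0])))
        assert best[0] == "101"

    def test_partial_dates_sort_as_earliest(self):
        demo = make_demo([("1", "X", "2020"), ("2", "X", "20200102")])
        assert list(pv.deduplicate(demo)["report_id"]) == ["2"]

    def test_idempotent_and_counts_cases(self, small_bundle):
        once = pv.deduplicate(small_bundle.demo)
        twice = pv.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) == small_bundle.demo["case_id"].nunique()
        assert set(once["case_id"]) == set(small_bundle.demo["case_id"])
        assert len(once) <= len(small_bundle.demo)

    def test_empty_input_returns_empty(self):
        empty = make_demo([])
        assert pv.deduplicate(empty).empty


@pytest.mark.parametrize("raw,expected", [
    ("HUMIRA 40 MG INJECTION", "humira"),
    ("etanercept", "etanercept"),
    ("  Enbrel.  ", "enbrel"),
    ("ENBREL 50MG/ML PREFILLED SYRINGE", "enbrel"),
    ("Actemra (tocilizumab) 162 mg solution", "actemra tocilizumab"),
    ("METHOTREXATE SODIUM TABLET", "methotrexate sodium"),
])
def test_normalize_name(raw, expected):
    assert pv.normalize_name(raw) == expected


class TestMapDrugs:
    def test_suspect_role_matches(self, case_def):
        drug = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "role_code": "PS", "verbatim_name": "Humira",
                              "active_ingredient": ""}])
        assert pv.map_drugs(drug, case_def) == {"1": {"adalimumab"}}

    def test_concomitant_only_maps_to_nothing(self, case_def):
        drug = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "role_code": "C", "verbatim_name": "Enbrel",
                              "active_ingredient": ""}])
        assert pv.map_drugs(drug, case_def) == {}

    def test_multiple_suspects_union(self, case_def):
        drug = pd.DataFrame([
            {"report_id": "1", "drug_seq": 1, "role_code": "PS",
             "verbatim_name": "Humira", "active_ingredient": ""},
            {"report_id": "1", "drug_seq": 2, "role_code": "SS",
             "verbatim_name": "Enbrel", "active_ingredient": ""}])
        assert pv.map_drugs(drug, case_def) == {
            "1": {"adalimumab", "etanercept"}}

    def test_active_ingredient_fallback(self, case_def):
        drug = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "role_code": "PS",
                              "verbatim_name": "UNKNOWN BRAND",
                              "active_ingredient": "adalimumab"}])
        assert pv.map_drugs(drug, case_def) == {"1": {"adalimumab"}}

    def test_ambiguous_synonym_is_configuration_error(self):
        with pytest.raises(pv.CaseConfigError, match="claimed by both"):
            pv.CaseDefinition(
                drug_dictionary={"a": {"Humira"}, "b": {"HUMIRA 40 MG"}},
                event_terms={"heart failure"})


class TestIndicationFilter:
    @pytest.fixture()
    def matches(self):
        return pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "drug_id": "adalimumab"}])

    def test_matching_indication_retained(self, matches, case_def):
        indi = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "indication_term": "Rheumatoid arthritis"}])
        out = pv.apply_indication_filter(matches, indi, case_def)
        assert len(out) == 1

    def test_wrong_indication_removed(self, matches, case_def):
        indi = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "indication_term": "Psoriasis"}])
        assert pv.apply_indication_filter(matches, indi, case_def).empty

    def test_indication_checked_per_drug_record(self, case_def):
        # the qualifying indication belongs to a different drug_seq
        matches = pd.DataFrame([{"report_id": "1", "drug_seq": 2,
                                 "drug_id": "adalimumab"}])
        indi = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "indication_term": "Rheumatoid arthritis"}])
        assert pv.apply_indication_filter(matches, indi, case_def).empty

    def test_disabled_filter_is_identity(self, matches):
        case_def = pv.CaseDefinition(
            drug_dictionary={"adalimumab": {"Humira"}},
            event_terms={"heart failure"}, indication_terms=set())
        indi = pd.DataFrame([{"report_id": "1", "drug_seq": 1,
                              "indication_term": "Psoriasis"}])
        out = pv.apply_indication_filter(matches, indi, case_def)
        pd.testing.assert_frame_equal(out, matches)


class TestFlagEvents:
    def reac(self, *terms):
        return pd.DataFrame([{"report_id": "1", "preferred_term": t}
                             for t in terms])

    def test_matching_term_included(self, case_def):
        assert pv.flag_events(self.reac("Cardiac failure"), case_def) == {"1"}

    def test_non_member_excluded(self, case_def):
        assert pv.flag_events(self.reac("Nausea"), case_def) == set()

    def test_any_match_over_report_terms(self, case_def):
        assert pv.flag_events(self.reac("Nausea", "heart failure"),
                              case_def) == {"1"}

    def test_exact_mode_rejects_longer_terms(self, case_def):
        assert pv.flag_events(self.reac("Cardiac failure congestive"),
                              case_def) == set()

    def test_substring_mode_captures_longer_terms(self, case_def):
        loose = pv.CaseDefinition(
            drug_dictionary=case_def.drug_dictionary,
            event_terms=case_def.event_terms,
            event_match_mode="substring")
        assert pv.flag_events(self.reac("Cardiac failure congestive"),
                              loose) == {"1"}


class TestClassifyOutcome:
    @pytest.mark.parametrize("codes,expected", [
        ({"DE", "HO"}, "death"),          # most serious wins
        ({"DS"}, "disability"),
        ({"CA"}, "disability"),
        ({"HO", "LT"}, "other-serious"),
        (set(), "none"),
    ])
    def test_examples(self, codes, expected):
        assert classify_outcome(codes) == expected

    def test_partitions_all_code_subsets(self):
        """Exhaustive: the four classes partition the 2^7 subsets."""
        seen = {"death": 0, "disability": 0, "other-serious": 0, "none": 0}
        codes = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
        for k in range(len(codes) + 1):
            for subset in itertools.combinations(codes, k):
                cls = classify_outcome(set(subset))
                seen[cls] += 1
                if "DE" in subset:
                    assert cls == "death"
        assert sum(seen.values()) == 2 ** 7
        assert seen["none"] == 1  # only the empty set

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            classify_outcome({"DE", "ZZ"})


class TestAge:
    @pytest.mark.parametrize("value,unit,expected", [
        (6, "MON", 0.5),
        (70, "YR", 70.0),
        (7, "DEC", 70.0),
        (730.5, "DY", 2.0),
        (52.1429, "WK", 1.0),
        (8766, "HR", 1.0),
    ])
    def test_unit_conversion(self, value, unit, expected):
        assert age_to_years(value, unit) == pytest.approx(expected)

    def test_unknown_unit_gives_missing(self):
        assert math.isnan(age_to_years(5, "XX"))

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            age_to_years(-1, "YR")

    @pytest.mark.parametrize("years,band", [
        (0.5, "<18"), (17.9, "<18"), (18, "18-44"), (44.9, "18-44"),
        (45, "45-64"), (64.9, "45-64"), (65, "65-74"), (74.9, "65-74"),
        (75, "75-84"), (84.9, "75-84"), (85, ">85"), (99, ">85"),
        (float("nan"), "unknown"),
    ])
    def test_age_bands(self, years, band):
        assert age_band(years) == band


class TestRegions:
    @pytest.mark.parametrize("country,region", [
        ("US", "North America"), ("United States", "North America"),
        ("GB", "Europe"), ("JP", "Asia"), ("BR", "South America"),
        ("AU", "Oceania"), ("NA", "Africa"),  # Namibia, not missing
        ("", "unknown"), ("ATLANTIS", "unknown"),
    ])
    def test_country_mapping(self, country, region):
        assert pv.country_to_region(country) == region

    def test_every_mapping_entry_hits_a_continent(self):
        assert set(_region_map().values()) == set(REGIONS) - {"unknown"}


@pytest.fixture(scope="module")
def fixture_bundle():
    """10 report versions: 8 cases, of which 2 are duplicated
    versions of other cases; among the 8 cases, 3 match only via a
    non-suspect role and 1 only with a wrong indication."""
    demo = make_demo([
        ("11", "A", "20190101"), ("12", "A", "20200101"),  # dup case
        ("21", "B", "20190601"), ("22", "B", "20190701"),  # dup case
        ("31", "C", "20190101"),   # good PS match
        ("41", "D", "20190101"),   # C-role match only
        ("51", "E", "20190101"),   # I-role match only
        ("61", "F", "20190101"),   # C-role match only
        ("71", "G", "20190101"),   # PS match, psoriasis indication
        ("81", "H", "20190101"),   # no target drug at all
    ])
    def drug_row(rid, role, name):
        return {"report_id": rid, "drug_seq": 1, "role_code": role,
                "verbatim_name": name, "active_ingredient": ""}
    drug = pd.DataFrame([
        drug_row("12", "PS", "Humira"), drug_row("22", "SS", "Enbrel"),
        drug_row("31", "PS", "Orencia"), drug_row("41", "C", "Humira"),
        drug_row("51", "I", "Enbrel"), drug_row("61", "C", "Actemra"),
        drug_row("71", "PS", "Humira"), drug_row("81", "PS", "aspirin"),
    ])
    indi = pd.DataFrame([
        {"report_id": rid, "drug_seq": 1, "indication_term": term}
        for rid, term in [("12", "Rheumatoid arthritis"),
                          ("22", "Rheumatoid arthritis"),
                          ("31", "Rheumatoid arthritis"),
                          ("41", "Rheumatoid arthritis"),
                          ("51", "Rheumatoid arthritis"),
                          ("61", "Rheumatoid arthritis"),
                          ("71", "Psoriasis"),
                          ("81", "Rheumatoid arthritis")]])
    reac = pd.DataFrame([
        {"report_id": rid, "preferred_term": t}
        for rid, t in [("12", "Cardiac failure"), ("22", "Nausea"),
                       ("31", "heart failure"), ("41", "Cardiac failure"),
                       ("51", "Nausea"), ("61", "Nausea"),
                       ("71", "Cardiac failure"), ("81", "Nausea")]])
    return pv.FaersBundle(demo=demo, drug=drug, reac=reac, indi=indi)

class TestAssembleCases:
    def test_hand_counted_survivors(self, fixture_bundle, case_def):
        cases = pv.assemble_cases(fixture_bundle, case_def, keep="all")
        assert len(cases) == 8  # distinct cases after dedup
        matched = pv.assemble_cases(fixture_bundle, case_def, keep="drug")
        # survivors: 12 (Humira PS), 22 (Enbrel SS), 31 (Orencia PS)
        assert sorted(matched["report_id"]) == ["12", "22", "31"]
        final = pv.assemble_cases(fixture_bundle, case_def,
                                  keep="drug_and_event")
        # 22 has no target event
        assert sorted(final["report_id"]) == ["12", "31"]

    def test_filters_are_monotone(self, fixture_bundle, case_def):
        sizes = [len(pv.assemble_cases(fixture_bundle, case_def, keep=k))
                 for k in ("all", "drug", "drug_and_event")]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_report_id_twice(self, small_bundle, case_def):
        cases = pv.assemble_cases(small_bundle, case_def)
        assert cases["report_id"].is_unique
        assert len(cases) == small_bundle.demo["case_id"].nunique()

    def test_case_tsv_round_trip(self, small_bundle, case_def, tmp_path):
        cases = pv.assemble_cases(small_bundle, case_def)
        path = pv.write_cases(cases, tmp_path / "cases.tsv")
        again = pv.read_cases(path)
        pd.testing.assert_frame_equal(cases, again)
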