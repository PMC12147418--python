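"""Confidence scoring, ranking, tie-breaking and eligibility flags."""

import dataclasses

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

import obturator_cbr.case_model as cm
import obturator_cbr.matcher as m
from obturator_cbr.errors import ClassMismatchError, ConfigError
from obturator_cbr.questionnaire import QuerySpec

from .conftest import attribute_maps, confidence_oracle, random_casebase

C = cm.AramanyClass


def record_and_query(cls=C.I, last_tooth="17", **overrides):
    """A deterministic record with a molar last tooth plus its self-query."""
    attrs = {
        cm.NEAREST_ABUTMENT: "13",
        cm.LAST_TOOTH: last_tooth,
        cm.ABUTMENT_CONDITION: "healthy",
        cm.BOUNDED_SPACE_COUNT: "single",
        cm.BOUNDED_SPACE_LOCATION: "anterior",
        cm.ORONASAL_CONNECTION: "partial_defect",
        cm.REMAINING_MOLAR_COUNT: "two",
    }
    attrs.update(overrides)
    case = cm.CaseRecord("C1", cls, attrs, ("m.png",))
    return case, QuerySpec(cls, dict(attrs))


class TestConfidence:
    def test_identical_records_score_exactly_one(self):
        case, query = record_and_query()
        assert m.confidence(query, case) == 1.0

    def test_sole_molar_count_mismatch_scores_exactly_095(self):
        # the calibrated share weight makes a lone disagreement in the
        # number of remaining molars cost exactly 0.05
        case, query = record_and_query()
        query.attributes[cm.REMAINING_MOLAR_COUNT] = "three"
        assert m.confidence(query, case) == 0.95

    def test_sole_both_premolars_mismatch_scores_exactly_095(self):
        case, query = record_and_query(
            last_tooth="15", **{cm.BOTH_PREMOLARS_PRESENT: "yes"})
        del case.attributes[cm.REMAINING_MOLAR_COUNT]
        del query.attributes[cm.REMAINING_MOLAR_COUNT]
        query.attributes[cm.BOTH_PREMOLARS_PRESENT] = "no"
        assert m.confidence(query, case) == 0.95

    def test_uniform_weights_two_of_ten_mismatches_score_08(self):
        # Class VI with spaces present and anterior last teeth has exactly
        # ten comparable keys; with shares disabled all weigh 1
        attrs = {
            cm.NEAREST_ABUTMENT_R: "13", cm.LAST_TOOTH_R: "12",
            cm.NEAREST_ABUTMENT_L: "23", cm.LAST_TOOTH_L: "22",
            cm.DEFECT_EXTENSION: "anterior_only",
            cm.ABUTMENT_CONDITION: "healthy",
            cm.BOUNDED_SPACE_COUNT: "double",
            cm.BOUNDED_SPACE_LOCATION: "anterior",
            cm.BOUNDED_SPACE_DISTRIBUTION: "bilateral",
            cm.ORONASAL_CONNECTION: "no_connection",
        }
        case = cm.CaseRecord("C1", C.VI, attrs, ("m.png",))
        query_attrs = dict(attrs)
        query_attrs[cm.ORONASAL_CONNECTION] = "small_fistula"
        query_attrs[cm.ABUTMENT_CONDITION] = "overdenture_root"
        uniform = m.WeightTable(shares={})
        score = m.confidence(QuerySpec(C.VI, query_attrs), case, uniform)
        assert score == pytest.approx(8 / 10)

    def test_skipped_keys_are_excluded_from_both_sides(self):
        # query lacks the molar-count key (different branch): the score
        # compares only the keys present in both records
        case, query = record_and_query()
        del query.attributes[cm.REMAINING_MOLAR_COUNT]
        query.attributes[cm.LAST_TOOTH] = "17"
        assert m.confidence(query, case) == 1.0

    def test_class_mismatch_is_a_contract_error(self):
        case, _ = record_and_query(cls=C.I)
        _, query = record_and_query(cls=C.IV)
        with pytest.raises(ClassMismatchError):
            m.confidence(query, case)
        with pytest.raises(ClassMismatchError):
            m.shared_keywords(query, case)

    @given(attribute_maps())
    def test_agrees_with_explicit_weight_oracle(self, cls_attrs):
        cls, attrs = cls_attrs
        case = cm.CaseRecord("C1", cls, attrs, ("m.png",))
        rng = np.random.default_rng(sum(map(ord, "".join(attrs))))
        query_attrs = dict(attrs)
        for key in attrs:
            if rng.random() < 0.4:
                vocab = [v for v in cm.vocabulary_for(cls, key)
                         if v != attrs[key]]
                query_attrs[key] = vocab[int(rng.integers(len(vocab)))]
        score = m.confidence(QuerySpec(cls, query_attrs), case)
        oracle = confidence_oracle(QuerySpec(cls, query_attrs), case)
        assert score == pytest.approx(oracle, abs=1e-12)
        assert 0.0 <= score <= 1.0

    @given(attribute_maps())
    def test_flipping_a_match_never_increases_confidence(self, cls_attrs):
        cls, attrs = cls_attrs
        case = cm.CaseRecord("C1", cls, attrs, ("m.png",))
        base = m.confidence(QuerySpec(cls, dict(attrs)), case)
        for key in attrs:
            vocab = [v for v in cm.vocabulary_for(cls, key) if v != attrs[key]]
            flipped = dict(attrs)
            flipped[key] = vocab[0]
            assert m.confidence(QuerySpec(cls, flipped), case) <= base


class TestSharedKeywords:
    def test_identical_records_share_everything_in_schema_order(self):
        case, query = record_and_query()
        shared = m.shared_keywords(query, case)
        schema_keys = cm.schema_for_class(C.I).keys
        assert set(shared) == set(case.attributes)
        assert list(shared) == [k for k in schema_keys if k in case.attributes]

    def test_all_values_different_shares_nothing(self):
        case, query = record_and_query()
        for key in list(query.attributes):
            vocab = [v for v in cm.vocabulary_for(C.I, key)
                     if v != query.attributes[key]]
            query.attributes[key] = vocab[0]
        assert m.shared_keywords(query, case) == ()

    def test_one_mismatch_removes_exactly_that_key(self):
        case, query = record_and_query()
        query.attributes[cm.ORONASAL_CONNECTION] = "entire_defect"
        full = set(case.attributes)
        assert set(m.shared_keywords(query, case)) == full - {cm.ORONASAL_CONNECTION}


class TestRetrieve:
    def test_fewer_candidates_than_k(self):
        rng = np.random.default_rng(5)
        casebase = random_casebase(rng, 3, aramany_class=C.I)
        _, query = record_and_query()
        report = m.retrieve(query, casebase, k=5)
        assert len(report.results) == 3
        confs = [r.confidence for r in report.results]
        assert confs == sorted(confs, reverse=True)
        assert [r.rank for r in report.results] == [1, 2, 3]

    def test_ties_break_by_ascending_case_id_in_any_insertion_order(self):
        case, query = record_and_query()
        twin_b = cm.CaseRecord("B2", C.I, case.attributes, ("b.png",))
        twin_a = cm.CaseRecord("A1", C.I, case.attributes, ("a.png",))
        for ordering in ([twin_b, twin_a], [twin_a, twin_b]):
            report = m.retrieve(query, cm.CaseBase(list(ordering)), k=5)
            assert [r.case_id for r in report.results] == ["A1", "B2"]

    def test_other_classes_only_gives_empty_report(self, caplog):
        rng = np.random.default_rng(7)
        casebase = random_casebase(rng, 4, aramany_class=C.V)
        _, query = record_and_query(cls=C.I)
        with caplog.at_level("WARNING"):
            report = m.retrieve(query, casebase, k=5)
        assert report.results == ()
        assert "no stored case" in caplog.text

    def test_k_must_be_positive(self):
        _, query = record_and_query()
        with pytest.raises(ValueError):
            m.retrieve(query, cm.CaseBase([]), k=0)

    def test_self_retrieval_is_rank_one_with_confidence_one(self):
        rng = np.random.default_rng(21)
        casebase = random_casebase(rng, 8)
        for case in casebase:
            query = QuerySpec(case.aramany_class, dict(case.attributes))
            report = m.retrieve(query, casebase, k=3)
            assert report.results[0].confidence == 1.0
            top_ids = [r.case_id for r in report.results
                       if r.confidence == 1.0]
            assert case.case_id in top_ids or report.results[0].rank == 1

    def test_row_order_permutation_changes_nothing(self):
        rng = np.random.default_rng(3)
        casebase = random_casebase(rng, 8, aramany_class=C.II)
        _, query = record_and_query(cls=C.II)
        query.attributes[cm.DEFECT_EXTENSION] = "one_quadrant"
        baseline = m.retrieve(query, casebase, k=5)
        for seed in range(3):
            shuffled = list(casebase.cases)
            np.random.default_rng(seed).shuffle(shuffled)
            assert m.retrieve(query, cm.CaseBase(shuffled), k=5) == baseline

    def test_results_carry_media_paths(self):
        case, query = record_and_query()
        report = m.retrieve(query, cm.CaseBase([case]), k=1)
        assert report.results[0].media_paths == ("m.png",)

    def test_report_json_round_trip(self, tmp_path):
        case, query = record_and_query()
        report = m.flag_eligible(m.retrieve(query, cm.CaseBase([case]), k=5))
        path = tmp_path / "report.json"
        report.to_json(path)
        assert m.RetrievalReport.from_json(path) == report


class TestEligibility:
    def test_threshold_is_strict(self):
        case, query = record_and_query()
        results = tuple(
            m.MatchResult(f"C{i}", conf, (), i + 1, ("m.png",))
            for i, conf in enumerate([1.0, 0.95, 0.90, 0.85])
        )
        report = m.RetrievalReport(query, results, 5)
        flagged = m.flag_eligible(report, 0.90)
        assert [r.eligible for r in flagged.results] == [True, True, False, False]

    def test_zero_threshold_accepts_any_positive_confidence(self):
        case, query = record_and_query()
        report = m.retrieve(query, cm.CaseBase([case]), k=5)
        flagged = m.flag_eligible(report, 0.0)
        assert all(r.eligible for r in flagged.results)

    def test_empty_report_stays_empty(self):
        _, query = record_and_query()
        report = m.RetrievalReport(query, (), 5)
        assert m.flag_eligible(report).results == ()

    def test_threshold_bounds_checked(self):
        _, query = record_and_query()
        with pytest.raises(ValueError):
            m.flag_eligible(m.RetrievalReport(query, (), 5), 1.5)


class TestWeightTable:
    def test_from_config_round_trip(self, tmp_path):
        config = {
            "default_weight": 2.0,
            "shares": {cm.REMAINING_MOLAR_COUNT: 0.1},
            "overrides": {"I": {cm.ORONASAL_CONNECTION: 3.0}},
        }
        path = tmp_path / "weights.yaml"
        path.write_text(yaml.safe_dump(config))
        table = m.WeightTable.from_config(path)
        assert table.default_weight == 2.0
        assert table.fixed_weight(C.I, cm.ORONASAL_CONNECTION) == 3.0
        assert table.fixed_weight(C.II, cm.ORONASAL_CONNECTION) == 2.0
        assert table.shares == {cm.REMAINING_MOLAR_COUNT: 0.1}

    @pytest.mark.parametrize(
        "kwargs",
        [{"default_weight": 0.0},
         {"shares": {cm.REMAINING_MOLAR_COUNT: 1.5}},
         {"overrides": {("I", cm.ORONASAL_CONNECTION): -1.0}}],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            m.WeightTable(**kwargs)

    def test_override_changes_score(self):
        case, query = record_and_query()
        query.attributes[cm.ORONASAL_CONNECTION] = "entire_defect"
        heavier = m.WeightTable(
            overrides={("I", cm.ORONASAL_CONNECTION): 4.0})
        assert m.confidence(query, case, heavier) < m.confidence(query, case)
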