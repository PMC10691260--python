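"""Evaluation templates, judgement recording, matrices and the case study."""

import io

import pytest

from scirapnano.bank import Part
from scirapnano.evaluation import (
    EvaluationError,
    MatrixFormatError,
    QualityRating,
    RelevanceRating,
    export_matrix,
    import_matrix,
    load_case_study_fixture,
    new_template,
    read_evaluation,
    read_evaluation_set,
    record_judgement,
    validate_evaluation,
    write_evaluation,
    write_evaluation_set,
)


class TestTemplate:
    def test_cell_line_study_keeps_all_criteria(self, bank_v2):
        ev = new_template(bank_v2, "S1", cell_line_based=True)
        assert len(ev.judged(Part.RQ)) == 38
        assert ev.removed == {}

    def test_non_cell_line_study_removes_conditional_criteria(self, bank_v2):
        ev = new_template(bank_v2, "S1", cell_line_based=False)
        assert set(ev.removed) == {(Part.RQ, 20), (Part.RQ, 26)}
        assert len(ev.judged(Part.RQ)) == 36
        for reason in ev.removed.values():
            assert "cell_line_only" in reason

    def test_v1_skeleton_template_has_33_rq_placeholders(self, bank_v1):
        ev = new_template(bank_v1, "S1")
        assert len(ev.judged(Part.RQ)) == 33
        assert all(j.rating is None for j in ev.judgements.values())


class TestRecordJudgement:
    def test_happy_path_stores_rating_and_comment(self, bank_v2):
        ev = new_template(bank_v2, "S1")
        record_judgement(ev, (Part.RQ, 5), "F", comment="TEM size given", bank=bank_v2)
        j = ev.judgements[(Part.RQ, 5)]
        assert j.rating is QualityRating.F and j.comment == "TEM size given"
        record_judgement(ev, (Part.RQ, 5), "PF", bank=bank_v2)  # overwrite keeps comment
        assert ev.judgements[(Part.RQ, 5)].rating is QualityRating.PF
        assert ev.judgements[(Part.RQ, 5)].comment == "TEM size given"

    def test_quality_token_on_relevance_item_is_scale_mismatch(self, bank_v2):
        ev = new_template(bank_v2, "S1")
        with pytest.raises(ValueError, match="not a valid rating"):
            record_judgement(ev, (Part.REL, 2), "F", bank=bank_v2)
        with pytest.raises(ValueError, match="not a valid rating"):
            record_judgement(ev, (Part.RQ, 1), "DR", bank=bank_v2)

    def test_rating_a_removed_criterion_fails(self, bank_v2):
        ev = new_template(bank_v2, "S1", cell_line_based=False)
        with pytest.raises(EvaluationError, match="removed"):
            record_judgement(ev, (Part.RQ, 20), "F", bank=bank_v2)

    def test_unknown_criterion_fails(self, bank_v2):
        ev = new_template(bank_v2, "S1")
        with pytest.raises(EvaluationError, match="unknown criterion RQ99"):
            record_judgement(ev, (Part.RQ, 99), "F", bank=bank_v2)


class TestValidateEvaluation:
    def test_blank_v1_template_reports_all_criteria_unrated(self, bank_v1):
        ev = new_template(bank_v1, "S1")
        violations = validate_evaluation(ev, bank_v1)
        assert len(violations) == 33 + 19 + 4
        assert {v.rule for v in violations} == {"unrated"}

    def test_unknown_id_violation(self, bank_v1):
        ev = load_case_study_fixture().get("Study 1").copy()
        from scirapnano.evaluation import CriterionJudgement
        ev.judgements[(Part.RQ, 99)] = CriterionJudgement((Part.RQ, 99), QualityRating.F)
        assert any(v.rule == "unknown-id" for v in validate_evaluation(ev, bank_v1))

    def test_judged_and_removed_is_inconsistent(self, bank_v2):
        ev = new_template(bank_v2, "S1", cell_line_based=True)
        for key, j in ev.judgements.items():
            j.rating = RelevanceRating.DR if key[0] is Part.REL else QualityRating.F
        ev.removed[(Part.RQ, 20)] = "late removal"
        rules = {v.rule for v in validate_evaluation(ev, bank_v2)}
        assert "judged-and-removed" in rules


class TestMatrixRoundTrip:
    @pytest.mark.parametrize("part", [Part.RQ, Part.MQ, Part.REL])
    def test_export_import_identity(self, part, bank_v1, case_study):
        text = export_matrix(case_study, part)
        back = import_matrix(io.StringIO(text), part, bank_v1)
        for orig, new in zip(case_study, back):
            assert orig.study_id == new.study_id
            assert {k: j.rating for k, j in orig.judged(part).items()} == \
                   {k: j.rating for k, j in new.judged(part).items()}

    def test_unknown_token_cites_row_and_column(self, bank_v1, case_study):
        text = export_matrix(case_study, Part.RQ).replace("RQ7,F", "RQ7,X", 1)
        with pytest.raises(MatrixFormatError, match=r"row 'RQ7', study 'Study 1'"):
            import_matrix(io.StringIO(text), Part.RQ, bank_v1)

    def test_empty_cell_is_missing_not_nd(self, bank_v1, case_study):
        text = export_matrix(case_study, Part.RQ).replace("RQ7,F", "RQ7,", 1)
        with pytest.raises(MatrixFormatError, match="empty cell"):
            import_matrix(io.StringIO(text), Part.RQ, bank_v1)

    def test_duplicate_study_columns_rejected(self, bank_v1):
        csv = "criterion_id,S1,S1\nRQ1,F,NF\n"
        with pytest.raises(MatrixFormatError, match="duplicate study column"):
            import_matrix(io.StringIO(csv), Part.RQ, bank_v1)

    def test_removed_cells_survive_round_trip(self, bank_v2):
        ev = new_template(bank_v2, "S1", cell_line_based=False)
        for key, j in ev.judgements.items():
            j.rating = RelevanceRating.DR if key[0] is Part.REL else QualityRating.F
        from scirapnano.evaluation import EvaluationSet
        text = export_matrix(EvaluationSet("2.0", [ev]), Part.RQ)
        back = import_matrix(io.StringIO(text), Part.RQ, bank_v2)
        assert set(back.evaluations[0].removed) == {(Part.RQ, 20), (Part.RQ, 26)}


class TestCaseStudyFixture:
    def test_eleven_complete_evaluations(self, case_study, bank_v1):
        assert len(case_study) == 11
        assert case_study.bank_version == "1.0-skeleton"
        for ev in case_study:
            assert validate_evaluation(ev, bank_v1) == []

    def test_matrix_dimensions(self, case_study):
        assert len(export_matrix(case_study, Part.RQ).strip().splitlines()) == 34  # header + 33
        assert len(export_matrix(case_study, Part.MQ).strip().splitlines()) == 20
        assert len(export_matrix(case_study, Part.REL).strip().splitlines()) == 5

    @pytest.mark.parametrize("study, part, cid, expected", [
        # every ND cell in the printed grids
        ("Study 11", Part.RQ, 19, "ND"),
        ("Study 11", Part.RQ, 24, "ND"),
        # every PF cell of the RQ grid
        ("Study 1", Part.RQ, 19, "PF"),
        ("Study 2", Part.RQ, 14, "PF"),
        ("Study 2", Part.RQ, 28, "PF"),
        ("Study 3", Part.RQ, 19, "PF"),
        ("Study 3", Part.RQ, 27, "PF"),
        ("Study 6", Part.RQ, 27, "PF"),
        ("Study 7", Part.RQ, 28, "PF"),
        ("Study 7", Part.RQ, 29, "PF"),
        ("Study 11", Part.RQ, 12, "PF"),
        ("Study 11", Part.RQ, 15, "PF"),
        # spot checks across all three grids
        ("Study 4", Part.MQ, 1, "NF"),
        ("Study 1", Part.RQ, 1, "F"),
        ("Study 2", Part.RQ, 2, "NF"),
        ("Study 5", Part.RQ, 12, "NF"),
        ("Study 8", Part.RQ, 21, "F"),
        ("Study 9", Part.RQ, 21, "NF"),
        ("Study 10", Part.RQ, 30, "F"),
        ("Study 3", Part.MQ, 2, "F"),
        ("Study 9", Part.MQ, 3, "PF"),
        ("Study 7", Part.MQ, 5, "NF"),
        ("Study 9", Part.MQ, 8, "NF"),
        ("Study 11", Part.MQ, 13, "PF"),
        ("Study 3", Part.MQ, 16, "F"),
        ("Study 2", Part.MQ, 16, "NF"),
        ("Study 7", Part.MQ, 18, "NF"),
        ("Study 4", Part.MQ, 19, "PF"),
        ("Study 3", Part.REL, 2, "IR"),
        ("Study 5", Part.REL, 2, "IR"),
        ("Study 2", Part.REL, 4, "IR"),
        ("Study 6", Part.REL, 4, "IR"),
        ("Study 7", Part.REL, 4, "IR"),
        ("Study 8", Part.REL, 4, "DR"),
    ])
    def test_cell_fidelity(self, case_study, study, part, cid, expected):
        assert case_study.get(study).rating(part, cid).value == expected

    def test_rq_row_multisets(self, case_study):
        """Each RQ row's rating tally matches the printed grid."""
        from collections import Counter
        expected = {
            1: {"F": 11}, 5: {"F": 11}, 12: {"NF": 10, "PF": 1}, 13: {"NF": 11},
            18: {"NF": 11}, 19: {"PF": 2, "F": 1, "NF": 7, "ND": 1},
            22: {"F": 1, "NF": 10}, 24: {"F": 8, "NF": 2, "ND": 1},
        }
        for cid, tally in expected.items():
            got = Counter(ev.rating(Part.RQ, cid).value for ev in case_study)
            assert got == Counter(tally), f"RQ{cid}"

    def test_relevance_has_no_not_relevant_cell(self, case_study):
        ratings = {j.rating for ev in case_study for j in ev.judged(Part.REL).values()}
        assert RelevanceRating.NR not in ratings
        assert ratings <= {RelevanceRating.DR, RelevanceRating.IR}

    def test_problem_formulation_recorded(self, case_study):
        for ev in case_study:
            assert "human health risk assessment" in ev.problem_formulation


class TestEvaluationFiles:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_evaluation_round_trip(self, tmp_path, bank_v2, suffix):
        ev = new_template(bank_v2, "S1", evaluator_id="e1", cell_line_based=False)
        record_judgement(ev, (Part.RQ, 5), "F", comment="ok", rationale="TEM", bank=bank_v2)
        back = read_evaluation(write_evaluation(ev, tmp_path / f"ev{suffix}"))
        assert back.study_id == "S1" and back.bank_version == "2.0"
        assert back.judgements[(Part.RQ, 5)].rating is QualityRating.F
        assert back.judgements[(Part.RQ, 5)].comment == "ok"
        assert set(back.removed) == {(Part.RQ, 20), (Part.RQ, 26)}

    def test_evaluation_set_round_trip(self, tmp_path, case_study):
        back = read_evaluation_set(write_evaluation_set(case_study, tmp_path / "set.json"))
        assert back.study_ids() == case_study.study_ids()
        for a, b in zip(case_study, back):
            assert {k: j.rating for k, j in a.judgements.items()} == \
                   {k: j.rating for k, j in b.judgements.items()}
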