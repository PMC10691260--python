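"""Per-study evaluations, rating matrices and the packaged case study.

A :class:`StudyEvaluation` is one evaluator's judgement of one study against
one bank version: a rating (plus optional comment and rationale) for every
applicable criterion, and a record of criteria removed because their
applicability condition failed (e.g. cell-passage criteria for studies not
conducted in a cell line). An :class:`EvaluationSet` stacks several studies
evaluated against the same bank version — exactly the criteria-by-studies
matrices the tool's colour charts are built from.

Quality criteria (RQ/MQ) use the F / PF / NF / ND vocabulary (fulfilled,
partially fulfilled, not fulfilled, not determined); relevance items use
DR / IR / NR / ND (directly / indirectly / not relevant, not determined).
An empty matrix cell is *missing data*, not ND: "not determined" is a
deliberate judgement and must be recorded explicitly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .bank import (
    BUILTIN_VERSIONS,
    Criterion,
    CriteriaBank,
    Part,
    RatingScale,
    Violation,
    load_builtin_bank,
)

__all__ = [
    "QualityRating",
    "RelevanceRating",
    "CriterionJudgement",
    "StudyEvaluation",
    "EvaluationSet",
    "EvaluationError",
    "MatrixFormatError",
    "new_template",
    "record_judgement",
    "validate_evaluation",
    "import_matrix",
    "export_matrix",
    "load_case_study_fixture",
    "read_evaluation",
    "write_evaluation",
    "read_evaluation_set",
    "write_evaluation_set",
    "rating_for",
]


class QualityRating(str, Enum):
    F = "F"     # fulfilled
    PF = "PF"   # partially fulfilled
    NF = "NF"   # not fulfilled
    ND = "ND"   # not determined


class RelevanceRating(str, Enum):
    DR = "DR"   # directly relevant
    IR = "IR"   # indirectly relevant
    NR = "NR"   # not relevant
    ND = "ND"   # not determined


def rating_for(part: Part | str, token) -> QualityRating | RelevanceRating:
    """Coerce a rating token to the vocabulary of ``part``.

    Raises ``ValueError`` on a token outside the part's closed vocabulary
    (including a quality token on a relevance item and vice versa).
    """
    part = Part(part)
    cls = RelevanceRating if part is Part.REL else QualityRating
    if isinstance(token, (QualityRating, RelevanceRating)) and not isinstance(token, cls):
        raise ValueError(f"{token.value!r} is a {type(token).__name__} token; "
                         f"{part.value} criteria use the {cls.__name__} scale")
    try:
        return cls(str(token.value if isinstance(token, Enum) else token).strip())
    except ValueError:
        raise ValueError(
            f"{token!r} is not a valid rating for part {part.value}; "
            f"expected one of {[r.value for r in cls]}") from None


class EvaluationError(ValueError):
    """Invalid operation on an evaluation (unknown id, removed criterion, scale mismatch...)."""


class MatrixFormatError(ValueError):
    """Malformed rating-matrix CSV; the message cites the offending row/column."""


@dataclass
class CriterionJudgement:
    """One rated criterion: the rating plus optional comment and rationale.

    ``rating`` is ``None`` in freshly created templates (an unrated
    placeholder); a complete evaluation has no ``None`` ratings left.
    """

    criterion_id: tuple  # (Part, id)
    rating: QualityRating | RelevanceRating | None = None
    comment: str | None = None
    rationale: str | None = None


@dataclass
class StudyEvaluation:
    """One evaluator's complete set of per-criterion judgements for one study."""

    study_id: str
    evaluator_id: str = ""
    bank_version: str = "2.0"
    problem_formulation: str = ""
    judgements: dict = field(default_factory=dict)  # (Part, id) -> CriterionJudgement
    removed: dict = field(default_factory=dict)     # (Part, id) -> reason

    def judged(self, part: Part | str) -> dict:
        part = Part(part)
        return {k: j for k, j in self.judgements.items() if k[0] is part}

    def rating(self, part: Part | str, cid: int):
        j = self.judgements.get((Part(part), cid))
        return None if j is None else j.rating

    def copy(self) -> "StudyEvaluation":
        return StudyEvaluation(
            study_id=self.study_id,
            evaluator_id=self.evaluator_id,
            bank_version=self.bank_version,
            problem_formulation=self.problem_formulation,
            judgements={k: CriterionJudgement(j.criterion_id, j.rating, j.comment, j.rationale)
                        for k, j in self.judgements.items()},
            removed=dict(self.removed),
        )


@dataclass
class EvaluationSet:
    """Ordered studies evaluated against one bank version; study ids unique."""

    bank_version: str
    evaluations: list = field(default_factory=list)

    def study_ids(self) -> list[str]:
        return [e.study_id for e in self.evaluations]

    def __len__(self) -> int:
        return len(self.evaluations)

    def __iter__(self):
        return iter(self.evaluations)

    def get(self, study_id: str) -> StudyEvaluation:
        for e in self.evaluations:
            if e.study_id == study_id:
                return e
        raise KeyError(study_id)

    def copy(self) -> "EvaluationSet":
        return EvaluationSet(self.bank_version, [e.copy() for e in self.evaluations])


def _bank_for(version: str, bank: CriteriaBank | None = None) -> CriteriaBank:
    if bank is not None:
        if bank.version != version:
            raise EvaluationError(f"evaluation targets bank {version!r} but bank {bank.version!r} was supplied")
        return bank
    if version in BUILTIN_VERSIONS:
        return load_builtin_bank(version)
    raise EvaluationError(f"no bank supplied and {version!r} is not a built-in version")


def new_template(
    bank: CriteriaBank,
    study_id: str,
    evaluator_id: str = "",
    problem_formulation: str = "",
    cell_line_based: bool = True,
) -> StudyEvaluation:
    """Blank evaluation: an unrated placeholder per applicable criterion.

    Criteria whose applicability condition fails the study metadata (today a
    single ``cell_line_based`` flag backing the ``cell_line_only`` condition)
    go into ``removed`` with an auto-generated reason and never enter any
    score denominator.
    """
    meta = {"cell_line_only": cell_line_based}
    ev = StudyEvaluation(study_id=study_id, evaluator_id=evaluator_id,
                         bank_version=bank.version, problem_formulation=problem_formulation)
    for c in bank.all_criteria():
        if c.applicability_condition is not None and not meta.get(c.applicability_condition, True):
            ev.removed[c.key] = f"auto-removed: condition {c.applicability_condition!r} not met by study metadata"
        else:
            ev.judgements[c.key] = CriterionJudgement(criterion_id=c.key)
    return ev


def record_judgement(
    ev: StudyEvaluation,
    criterion_id: tuple,
    rating,
    comment: str | None = None,
    rationale: str | None = None,
    bank: CriteriaBank | None = None,
) -> StudyEvaluation:
    """Store (or overwrite) one judgement on ``ev`` and return it.

    Rejects unknown criterion ids, ratings on removed criteria, and rating
    tokens from the wrong vocabulary for the criterion's scale.
    """
    part, cid = Part(criterion_id[0]), int(criterion_id[1])
    key = (part, cid)
    if key in ev.removed:
        raise EvaluationError(f"criterion {part.value}{cid} was removed from this evaluation "
                              f"({ev.removed[key]}) and cannot be rated")
    resolved = _bank_for(ev.bank_version, bank)
    if not resolved.has(part, cid):
        raise EvaluationError(f"unknown criterion {part.value}{cid} for bank {ev.bank_version!r}")
    coerced = rating_for(part, rating)
    j = ev.judgements.get(key) or CriterionJudgement(criterion_id=key)
    j.rating = coerced
    if comment is not None:
        j.comment = comment
    if rationale is not None:
        j.rationale = rationale
    ev.judgements[key] = j
    return ev


def validate_evaluation(ev: StudyEvaluation, bank: CriteriaBank | None = None) -> list[Violation]:
    """Violations preventing ``ev`` from being a complete, consistent evaluation.

    Empty iff every non-removed criterion of every part is rated with a token
    from the right vocabulary and no judgement refers to an unknown or
    removed criterion.
    """
    out: list[Violation] = []
    try:
        resolved = _bank_for(ev.bank_version, bank)
    except EvaluationError as exc:
        return [Violation(None, None, "unknown-bank", str(exc))]

    for (part, cid), j in ev.judgements.items():
        if not resolved.has(part, cid):
            out.append(Violation(part.value, cid, "unknown-id",
                                 f"judgement refers to unknown criterion {part.value}{cid}"))
            continue
        if (part, cid) in ev.removed:
            out.append(Violation(part.value, cid, "judged-and-removed",
                                 "criterion is both judged and removed"))
        if j.rating is None:
            out.append(Violation(part.value, cid, "unrated", "criterion has no rating"))
        else:
            expected = RelevanceRating if part is Part.REL else QualityRating
            if not isinstance(j.rating, expected):
                out.append(Violation(part.value, cid, "scale-mismatch",
                                     f"rating {j.rating} is not on the {expected.__name__} scale"))
    for part, cid in ev.removed:
        if not resolved.has(part, cid):
            out.append(Violation(part.value, cid, "unknown-id",
                                 f"removed entry refers to unknown criterion {part.value}{cid}"))
    for c in resolved.all_criteria():
        if c.key not in ev.judgements and c.key not in ev.removed:
            out.append(Violation(c.part.value, c.id, "missing",
                                 f"criterion {c.label()} is neither judged nor removed"))
    return out


# --- rating-matrix CSV import/export ----------------------------------------

def export_matrix(evalset: EvaluationSet, part: Part | str, path_or_buf=None) -> str:
    """Write one part of an evaluation set as a criteria-by-studies CSV.

    First column ``criterion_id`` holds ``RQ5``-style labels; one column per
    study; cells are rating tokens. Removed criteria export as ``REMOVED``.
    Returns the CSV text (and writes it to ``path_or_buf`` when given).
    """
    part = Part(part)
    keys = sorted({k for ev in evalset for k in (*ev.judgements, *ev.removed) if k[0] is part},
                  key=lambda k: k[1])
    rows = []
    for p, cid in keys:
        row = {"criterion_id": f"{p.value}{cid}"}
        for ev in evalset:
            if (p, cid) in ev.removed:
                row[ev.study_id] = "REMOVED"
            else:
                r = ev.rating(p, cid)
                row[ev.study_id] = "" if r is None else r.value
        rows.append(row)
    df = pd.DataFrame(rows, columns=["criterion_id", *evalset.study_ids()])
    text = df.to_csv(index=False)
    if path_or_buf is not None:
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            Path(path_or_buf).write_text(text, encoding="utf-8")
    return text


def import_matrix(path_or_buf, part: Part | str, bank: CriteriaBank) -> EvaluationSet:
    """Read a criteria-by-studies CSV into an :class:`EvaluationSet`.

    Unknown rating tokens are rejected with the offending criterion row and
    study column named; duplicate study columns and criterion rows are
    errors. Only the requested part is populated, so the resulting
    evaluations are partial unless the CSV covers a whole part.
    """
    part = Part(part)
    if hasattr(path_or_buf, "read"):
        df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(Path(path_or_buf), dtype=str, keep_default_na=False)
    if df.columns[0] != "criterion_id":
        raise MatrixFormatError("first column must be 'criterion_id'")
    studies = list(df.columns[1:])
    if len(set(studies)) != len(studies) or any(s.endswith(".1") for s in studies):
        raise MatrixFormatError("duplicate study column names in header")
    if not studies:
        raise MatrixFormatError("matrix has no study columns")

    evals = {s: StudyEvaluation(study_id=s, bank_version=bank.version) for s in studies}
    seen_rows: set[int] = set()
    for _, row in df.iterrows():
        label = str(row["criterion_id"]).strip()
        prefix = part.value
        if not label.startswith(prefix) or not label[len(prefix):].isdigit():
            raise MatrixFormatError(f"row {label!r}: expected a {prefix}<id> criterion label")
        cid = int(label[len(prefix):])
        if cid in seen_rows:
            raise MatrixFormatError(f"row {label!r}: duplicate criterion row")
        seen_rows.add(cid)
        if not bank.has(part, cid):
            raise MatrixFormatError(f"row {label!r}: unknown criterion for bank {bank.version!r}")
        for s in studies:
            token = str(row[s]).strip()
            if token == "REMOVED":
                evals[s].removed[(part, cid)] = "removed in imported matrix"
                continue
            if token == "":
                raise MatrixFormatError(
                    f"row {label!r}, study {s!r}: empty cell (missing data; use ND for 'not determined')")
            try:
                rating = rating_for(part, token)
            except ValueError as exc:
                raise MatrixFormatError(f"row {label!r}, study {s!r}: {exc}") from None
            evals[s].judgements[(part, cid)] = CriterionJudgement((part, cid), rating)
    return EvaluationSet(bank_version=bank.version, evaluations=[evals[s] for s in studies])


# --- packaged case study -----------------------------------------------------

#: Problem formulation under which the packaged case study's relevance was judged.
CASE_STUDY_PROBLEM = "human health risk assessment of nano-size TiO2 in real-life exposure level"


def load_case_study_fixture() -> EvaluationSet:
    """The packaged titanium-dioxide case study: 11 in vitro studies rated
    against tool version 1.0 (33 RQ criteria, 19 MQ criteria, 4 relevance
    items), reproduced cell-for-cell from the published rating matrices.
    """
    bank = load_builtin_bank("1.0-skeleton")
    parts = {Part.RQ: "case-study-rq.csv", Part.MQ: "case-study-mq.csv", Part.REL: "case-study-rel.csv"}
    merged: dict[str, StudyEvaluation] = {}
    order: list[str] = []
    for part, fname in parts.items():
        ref = resources.files("scirapnano.data") / fname
        sub = import_matrix(io.StringIO(ref.read_text(encoding="utf-8")), part, bank)
        for ev in sub:
            if ev.study_id not in merged:
                merged[ev.study_id] = StudyEvaluation(
                    study_id=ev.study_id,
                    evaluator_id="case-study evaluator",
                    bank_version=bank.version,
                    problem_formulation=CASE_STUDY_PROBLEM,
                )
                order.append(ev.study_id)
            merged[ev.study_id].judgements.update(ev.judgements)
    return EvaluationSet(bank_version=bank.version, evaluations=[merged[s] for s in order])


# --- full-evaluation JSON/YAML files -----------------------------------------

def _ev_to_dict(ev: StudyEvaluation) -> dict:
    def jd(j: CriterionJudgement) -> dict:
        d: dict = {"rating": None if j.rating is None else j.rating.value}
        if j.comment:
            d["comment"] = j.comment
        if j.rationale:
            d["rationale"] = j.rationale
        return d

    return {
        "study_id": ev.study_id,
        "evaluator_id": ev.evaluator_id,
        "bank_version": ev.bank_version,
        "problem_formulation": ev.problem_formulation,
        "judgements": {f"{p.value}{cid}": jd(j) for (p, cid), j in ev.judgements.items()},
        "removed": {f"{p.value}{cid}": reason for (p, cid), reason in ev.removed.items()},
    }


def _ev_from_dict(data: Mapping, source: str) -> StudyEvaluation:
    for req in ("study_id", "bank_version", "judgements"):
        if req not in data:
            raise EvaluationError(f"{source}: missing required field {req!r}")
    ev = StudyEvaluation(
        study_id=str(data["study_id"]),
        evaluator_id=str(data.get("evaluator_id", "")),
        bank_version=str(data["bank_version"]),
        problem_formulation=str(data.get("problem_formulation", "")),
    )
    import re as _re
    for label, j in (data.get("judgements") or {}).items():
        m = _re.fullmatch(r"(RQ|MQ|REL)(\d+)", label)
        if not m:
            raise EvaluationError(f"{source}: bad criterion label {label!r}")
        part, cid = Part(m.group(1)), int(m.group(2))
        raw = j.get("rating") if isinstance(j, Mapping) else j
        rating = None if raw in (None, "") else rating_for(part, raw)
        ev.judgements[(part, cid)] = CriterionJudgement(
            (part, cid), rating,
            comment=j.get("comment") if isinstance(j, Mapping) else None,
            rationale=j.get("rationale") if isinstance(j, Mapping) else None,
        )
    for label, reason in (data.get("removed") or {}).items():
        m = _re.fullmatch(r"(RQ|MQ|REL)(\d+)", label)
        if not m:
            raise EvaluationError(f"{source}: bad criterion label {label!r}")
        ev.removed[(Part(m.group(1)), int(m.group(2)))] = str(reason)
    return ev


def write_evaluation(ev: StudyEvaluation, path: str | Path) -> Path:
    path = Path(path)
    data = _ev_to_dict(ev)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    return path


def read_evaluation(path: str | Path) -> StudyEvaluation:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml") else json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise EvaluationError(f"{path}: cannot parse: {exc}") from exc
    return _ev_from_dict(data, str(path))


def write_evaluation_set(evalset: EvaluationSet, path: str | Path) -> Path:
    path = Path(path)
    data = {"bank_version": evalset.bank_version, "evaluations": [_ev_to_dict(e) for e in evalset]}
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    return path


def read_evaluation_set(path: str | Path) -> EvaluationSet:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml") else json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise EvaluationError(f"{path}: cannot parse: {exc}") from exc
    if "bank_version" not in data or "evaluations" not in data:
        raise EvaluationError(f"{path}: missing 'bank_version' or 'evaluations'")
    evs = [_ev_from_dict(e, f"{path}[{i}]") for i, e in enumerate(data["evaluations"])]
    ids = [e.study_id for e in evs]
    if len(set(ids)) != len(ids):
        raise EvaluationError(f"{path}: duplicate study ids")
    for e in evs:
        if e.bank_version != data["bank_version"]:
            raise EvaluationError(f"{path}: evaluation {e.study_id!r} targets bank {e.bank_version!r}, "
                                  f"set targets {data['bank_version']!r}")
    return EvaluationSet(bank_version=str(data["bank_version"]), evaluations=evs)
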