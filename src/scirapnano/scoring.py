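"""Reliability scores and cross-study summaries.

Reporting quality and methodological quality are scored separately on a
0–100 scale; relevance is deliberately never reduced to a number and is
summarised as a qualitative colour profile instead.

The numeric score is a weighted fulfilment fraction

    score = 100 * (n_F * w_F + n_PF * w_PF + n_NF * w_NF) / denominator

with default weights w_F = 1, w_PF = 0.5, w_NF = 0. "Not determined" (ND)
ratings are excluded from the denominator by default (they carry no
information about quality either way); the alternative ``count_as_zero``
policy treats ND as harshly as NF. Criteria removed for inapplicability
never enter the denominator under either policy. The weights and ND policy
are an explicit, overridable convention of this package: the tool's
published description fixes only that a numeric score exists, not its
arithmetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .bank import CriteriaBank, Part
from .evaluation import (
    EvaluationSet,
    QualityRating,
    RelevanceRating,
    StudyEvaluation,
    validate_evaluation,
)

__all__ = [
    "ScoreWeights",
    "ScoreResult",
    "CriterionSummary",
    "IncompleteEvaluationError",
    "DEFAULT_WEIGHTS",
    "quality_score",
    "criterion_summary",
    "zero_fulfilled",
    "least_fulfilled_ranking",
    "relevance_profile",
]


class IncompleteEvaluationError(ValueError):
    """Scoring requested on an evaluation with unrated criteria."""


@dataclass(frozen=True)
class ScoreWeights:
    """Per-rating weights and the ND (not determined) denominator policy.

    Weights must lie in [0, 1] and be monotone (F >= PF >= NF) so that a
    better rating can never lower a score.
    """

    f: float = 1.0
    pf: float = 0.5
    nf: float = 0.0
    nd_policy: str = "exclude_from_denominator"  # or "count_as_zero"

    def __post_init__(self) -> None:
        for name, w in (("f", self.f), ("pf", self.pf), ("nf", self.nf)):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {name}={w} outside [0, 1]")
        if not self.f >= self.pf >= self.nf:
            raise ValueError(f"weights must satisfy f >= pf >= nf, got {self.f}, {self.pf}, {self.nf}")
        if self.nd_policy not in ("exclude_from_denominator", "count_as_zero"):
            raise ValueError(f"unknown nd_policy {self.nd_policy!r}")

    def weight(self, rating: QualityRating) -> float:
        return {QualityRating.F: self.f, QualityRating.PF: self.pf,
                QualityRating.NF: self.nf, QualityRating.ND: 0.0}[rating]


DEFAULT_WEIGHTS = ScoreWeights()


@dataclass(frozen=True)
class ScoreResult:
    """A 0–100 reliability score with its tallies and section breakdown.

    ``score`` is ``None`` when the denominator is zero (e.g. every criterion
    ND under the default policy): undefined, not 0 or 100.
    """

    part: Part
    score: float | None
    counts: dict
    denominator: int
    per_section: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 1) -> float | None:
        return None if self.score is None else round(self.score, ndigits)


def _score_ratings(ratings, weights: ScoreWeights) -> tuple[float | None, Counter, int]:
    counts = Counter(r.value for r in ratings)
    for r in QualityRating:
        counts.setdefault(r.value, 0)
    denom = sum(counts.values())
    if weights.nd_policy == "exclude_from_denominator":
        denom -= counts[QualityRating.ND.value]
    if denom == 0:
        return None, counts, 0
    total = sum(weights.weight(QualityRating(r.value)) * n
                for r, n in ((QualityRating(k), v) for k, v in counts.items()))
    return 100.0 * total / denom, counts, denom


def quality_score(
    ev: StudyEvaluation,
    part: Part | str,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    bank: CriteriaBank | None = None,
) -> ScoreResult:
    """Score one study's RQ or MQ part (relevance is never scored).

    Requires a complete part: every non-removed criterion rated. When the
    bank is resolvable (built-in version or passed explicitly) a per-section
    breakdown is included, each section scored under the same weights.
    """
    part = Part(part)
    if part is Part.REL:
        raise ValueError("relevance is evaluated qualitatively and has no numeric score")
    judged = ev.judged(part)
    unrated = sorted(cid for (p, cid), j in judged.items() if j.rating is None)
    if unrated:
        raise IncompleteEvaluationError(
            f"{ev.study_id}: cannot score incomplete {part.value} evaluation; "
            f"unrated criteria: {', '.join(f'{part.value}{i}' for i in unrated)}")
    if not judged:
        raise IncompleteEvaluationError(f"{ev.study_id}: no {part.value} judgements to score")

    score, counts, denom = _score_ratings([j.rating for j in judged.values()], weights)

    per_section: dict[str, float | None] = {}
    try:
        from .evaluation import _bank_for
        resolved = _bank_for(ev.bank_version, bank)
    except Exception:
        resolved = None
    if resolved is not None:
        for section in resolved.sections(part):
            ratings = [judged[c.key].rating for c in resolved.part(part)
                       if c.section == section and c.key in judged]
            if ratings:
                s, _, _ = _score_ratings(ratings, weights)
                per_section[section] = s
    return ScoreResult(part=part, score=score, counts=dict(counts), denominator=denom,
                       per_section=per_section)


@dataclass(frozen=True)
class CriterionSummary:
    """Cross-study tally for one criterion: how often each rating was given."""

    criterion_id: tuple  # (Part, id)
    counts: dict         # rating token -> count over studies
    fulfilled_fraction: float | None

    @property
    def f_count(self) -> int:
        return self.counts.get("F", 0)

    @property
    def pf_count(self) -> int:
        return self.counts.get("PF", 0)


def _require_complete(evalset: EvaluationSet, part: Part) -> None:
    if not evalset.evaluations:
        return
    versions = {e.bank_version for e in evalset}
    if len(versions) > 1 or (evalset.bank_version not in versions):
        raise ValueError(f"mixed bank versions in evaluation set: {sorted(versions)}")
    for ev in evalset:
        unrated = [cid for (p, cid), j in ev.judged(part).items() if j.rating is None]
        if unrated:
            raise IncompleteEvaluationError(
                f"{ev.study_id}: unrated {part.value} criteria: {sorted(unrated)}")


def criterion_summary(evalset: EvaluationSet, part: Part | str) -> list[CriterionSummary]:
    """Per-criterion rating tallies across all studies, ordered by id."""
    part = Part(part)
    _require_complete(evalset, part)
    ids = sorted({cid for ev in evalset for (p, cid) in ev.judged(part)})
    out = []
    for cid in ids:
        ratings = [ev.rating(part, cid) for ev in evalset if (part, cid) in ev.judgements]
        counts = Counter(r.value for r in ratings)
        n = len(ratings)
        out.append(CriterionSummary(
            criterion_id=(part, cid),
            counts=dict(counts),
            fulfilled_fraction=(counts.get("F", 0) / n) if n else None,
        ))
    return out


def zero_fulfilled(evalset: EvaluationSet, part: Part | str) -> set[int]:
    """Criterion ids never rated F (fulfilled) in any study."""
    return {cid for (p, cid), s in ((s.criterion_id, s) for s in criterion_summary(evalset, part))
            if s.f_count == 0}


def least_fulfilled_ranking(evalset: EvaluationSet, part: Part | str, k: int) -> list[int]:
    """The ``k`` least-fulfilled criteria: ascending F count, ties broken by
    ascending PF count, then by id."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    summaries = criterion_summary(evalset, part)
    ranked = sorted(summaries, key=lambda s: (s.f_count, s.pf_count, s.criterion_id[1]))
    return [s.criterion_id[1] for s in ranked[:k]]


def relevance_profile(evalset: EvaluationSet, bank: CriteriaBank | None = None):
    """Qualitative relevance profile: a colour matrix plus per-item counts.

    Returns ``(ColorMatrix, counts)`` where ``counts`` maps item id to a
    rating-token tally. No numeric score is produced for relevance.
    """
    from .reporting import build_color_matrix

    _require_complete(evalset, Part.REL)
    matrix = build_color_matrix(evalset, Part.REL, bank=bank)
    counts = {s.criterion_id[1]: s.counts for s in criterion_summary(evalset, Part.REL)}
    return matrix, counts
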