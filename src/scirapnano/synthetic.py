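"""Seeded synthetic evaluation sets for property testing.

Ratings are drawn independently per cell from a user-supplied categorical
distribution over the quality vocabulary (and another over the relevance
vocabulary), using numpy's seeded PCG64 generator so identical inputs give
identical evaluation sets on any platform. Real evaluations are correlated
(e.g. physicochemical criteria tend to be co-missing); independent sampling
is deliberate — it is all the scoring and rendering properties need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bank import CriteriaBank, Part
from .evaluation import (
    CriterionJudgement,
    EvaluationSet,
    QualityRating,
    RelevanceRating,
    StudyEvaluation,
    new_template,
)

__all__ = ["RatingDistribution", "generate_evaluations", "perturb"]


@dataclass(frozen=True)
class RatingDistribution:
    """Cell-level rating probabilities.

    ``quality`` maps F/PF/NF/ND tokens to probabilities (unlisted tokens get
    0) and likewise ``relevance`` for DR/IR/NR/ND; each must sum to 1.
    ``overrides`` optionally fixes a different quality distribution for
    individual criteria, keyed by ``(Part, id)``.
    """

    quality: dict = field(default_factory=lambda: {"F": 0.6, "PF": 0.2, "NF": 0.15, "ND": 0.05})
    relevance: dict = field(default_factory=lambda: {"DR": 0.7, "IR": 0.2, "NR": 0.05, "ND": 0.05})
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check(self.quality, [r.value for r in QualityRating], "quality")
        self._check(self.relevance, [r.value for r in RelevanceRating], "relevance")
        for key, dist in self.overrides.items():
            self._check(dist, [r.value for r in QualityRating], f"override {key}")

    @staticmethod
    def _check(dist: dict, vocab: list[str], name: str) -> None:
        unknown = set(dist) - set(vocab)
        if unknown:
            raise ValueError(f"{name} distribution has unknown tokens {sorted(unknown)}")
        if any(p < 0 for p in dist.values()):
            raise ValueError(f"{name} distribution has negative probabilities")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{name} distribution sums to {total}, not 1")

    def probs(self, part: Part, cid: int) -> tuple[list[str], list[float]]:
        if part is Part.REL:
            vocab, dist = [r.value for r in RelevanceRating], self.relevance
        else:
            vocab = [r.value for r in QualityRating]
            dist = self.overrides.get((part, cid), self.quality)
        return vocab, [dist.get(t, 0.0) for t in vocab]


def generate_evaluations(
    bank: CriteriaBank,
    n_studies: int,
    dist: RatingDistribution | None = None,
    seed: int = 0,
    cell_line_based: bool = True,
    with_comments: bool = False,
) -> EvaluationSet:
    """``n_studies`` complete evaluations with ids ``SYN-001``, ``SYN-002``, ...

    Identical ``(bank, n_studies, dist, seed)`` yield identical sets. The
    bank is never mutated. ``with_comments`` attaches an ``auto`` marker
    comment to every judgement to exercise report pass-through.
    """
    if n_studies < 0:
        raise ValueError(f"n_studies must be >= 0, got {n_studies}")
    dist = dist or RatingDistribution()
    rng = np.random.default_rng(seed)
    evaluations = []
    for i in range(n_studies):
        ev = new_template(bank, study_id=f"SYN-{i + 1:03d}", evaluator_id="synthetic",
                          cell_line_based=cell_line_based)
        for (part, cid), j in ev.judgements.items():
            vocab, p = dist.probs(part, cid)
            token = vocab[int(rng.choice(len(vocab), p=p))]
            j.rating = RelevanceRating(token) if part is Part.REL else QualityRating(token)
            if with_comments:
                j.comment = f"auto comment {part.value}{cid}"
        evaluations.append(ev)
    return EvaluationSet(bank_version=bank.version, evaluations=evaluations)


_UPGRADE = {QualityRating.NF: QualityRating.PF, QualityRating.PF: QualityRating.F}


def perturb(evalset: EvaluationSet, n_upgrades: int, seed: int = 0) -> tuple[EvaluationSet, int]:
    """Apply ``n_upgrades`` random single-step rating upgrades (NF→PF, PF→F).

    Used to assert score monotonicity. Cells already at F (or rated ND) are
    not upgradable; if fewer than ``n_upgrades`` upgradable cells exist the
    surplus is skipped. Returns ``(perturbed copy, upgrades actually applied)``;
    the input set is untouched.
    """
    if n_upgrades < 0:
        raise ValueError(f"n_upgrades must be >= 0, got {n_upgrades}")
    out = evalset.copy()
    rng = np.random.default_rng(seed)
    applied = 0
    for _ in range(n_upgrades):
        candidates = [(ev, key) for ev in out for key, j in ev.judgements.items()
                      if isinstance(j.rating, QualityRating) and j.rating in _UPGRADE]
        if not candidates:
            break
        ev, key = candidates[int(rng.integers(len(candidates)))]
        j = ev.judgements[key]
        j.rating = _UPGRADE[j.rating]
        applied += 1
    return out, applied
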