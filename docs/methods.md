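# Methods

## The evaluation model

A *criteria bank* is a versioned, ordered checklist in three parts —
reporting quality (RQ), methodological quality (MQ) and relevance (REL) —
plus two registries that tie criteria back to the concepts they encode: the
11 key physicochemical parameters of a nanomaterial, the 8
nanomaterial-specific aspects of in vitro testing, and the 4 low-priority
properties folded into the open "other information" RQ criterion. A
*study evaluation* assigns each applicable criterion one rating from a
closed vocabulary (F/PF/NF/ND for quality, DR/IR/NR/ND for relevance),
optionally with a free-text comment and rationale. Evaluation is a human
judgement; the package models, validates, scores and renders it, and never
attempts to rate a study from its text.

Two built-in banks:

- **2.0** — the full tool: 38 RQ / 19 MQ / 4 REL, with verbatim wording,
  provenance flags (15 RQ and 3 MQ criteria are new nanomaterial-specific
  additions; MQ#2 replaced the original solubility criterion, which is
  meaningless for particles that are not generally soluble), applicability
  conditions, and populated registries.
- **1.0-skeleton** — ids and section labels of tool version 1.0
  (33 RQ / 19 MQ / 4 REL), the version the packaged case study was rated
  against. The 1.0 wordings were published as supplementary material and are
  not redistributed here; every entry carries a text-unavailable marker, and
  the case-study fixture is keyed by id only. MQ#16 (physicochemical
  characterization "as received / as administered / in situ"), whose wording
  is known, is annotated in guidance but has no stated 2.0 successor and is
  not mapped forward. Registry-count invariants (11/8/4) are enforced for
  version 2.0 only; the skeleton ships empty registries rather than invented
  mappings.

Registry subtleties: *stability* is not a standalone criterion — it overlaps
agglomeration state and solubility, so the registry maps it to both RQ#12
and RQ#13 while *solubility* and *dissolution rate* map jointly to RQ#12;
the registry keeps 11 named parameters over 9 distinct criteria. The
low-priority properties (delivery form, dustiness, viscosity, labelling)
all map to the open criterion RQ#38.

## Applicability and removal

Two RQ criteria (#20 cell passages, #26 cell density) carry the
`cell_line_only` condition. Templates built with `cell_line_based=False`
move them to the evaluation's `removed` mapping with an auto-generated
reason; removed criteria can never be rated, never enter a score
denominator, and render as a hatched "removed" cell distinct from grey ND —
removal is an applicability fact, not a judgement. Study metadata is
currently the single boolean behind that one condition; richer predicates
would slot into the same mechanism.

An **empty matrix cell is missing data, not ND**: "not determined" is a
deliberate judgement and must be written explicitly. Import rejects empty
cells with the offending row and column named.

## Scoring

The published description of the tool fixes *that* RQ and MQ are summarized
with a numerical score and that relevance is presented only as a colour
profile; it does not print the score arithmetic. The package therefore
declares its convention explicitly and keeps it overridable
(`ScoreWeights`):

- weights F = 1, PF = 0.5, NF = 0 — the simplest monotone scheme consistent
  with a three-level fulfilment scale; any weights in [0, 1] with
  F ≥ PF ≥ NF are accepted;
- score = 100 · Σ weight(rating) / denominator, reported per part (RQ and MQ
  separately — no combined reliability number is offered, since merging them
  would invent semantics the method does not define) and per section;
- ND policy: `exclude_from_denominator` (default — an ND rating carries no
  information about quality either way, so the score equals the score of the
  determined criteria) or `count_as_zero` (conservative); a denominator of
  zero yields an undefined score (`None`), never 0 or 100;
- displays round to 1 decimal; full precision is kept internally.

These choices give three provable invariants, all property-tested: scores
lie in [0, 100]; upgrading any single rating along NF→PF→F never decreases
a score; and under the default policy re-rating a criterion to ND yields
exactly the score of the remaining criteria. This is a convention of this
package, not a claim about the arithmetic of any external platform.

Cross-study summaries tally ratings per criterion over an evaluation set.
"Least fulfilled" ranks by ascending F count, ties by ascending PF count,
then by id — so a criterion with no F and no PF ranks below one with no F
but a PF somewhere.

## The packaged case study

Eleven published in vitro studies of nano-sized titanium dioxide, rated by a
single evaluator against tool version 1.0 under the problem formulation
"human health risk assessment of nano-size TiO2 in real-life exposure
level", are shipped as three CSV matrices (33×11 RQ, 19×11 MQ, 4×11
relevance) and loaded into complete, validated evaluations. The fixture
reproduces the published grids cell for cell; tests assert every PF and ND
cell, row tallies, and the headline findings (size is the only fully
reported physicochemical parameter; solubility, dissolution rate and
metabolic competence are never fulfilled; MQ#16 is the least fulfilled MQ
criterion; relevance items 1 and 3 are directly relevant everywhere and no
item was ever judged not relevant).

## Synthetic evaluations

`generate_evaluations` draws each cell independently from a categorical
distribution over the quality vocabulary (and a second one over the
relevance vocabulary), with optional per-criterion overrides, using numpy's
seeded PCG64 generator; identical inputs give identical sets on any
platform, study ids are `SYN-001`, `SYN-002`, … and the bank is never
mutated. Defaults (F 0.6, PF 0.2, NF 0.15, ND 0.05 quality; DR 0.7, IR 0.2,
NR 0.05, ND 0.05 relevance) describe a moderately well-reported literature,
in line with the case study where most criteria are fulfilled and ND is
rare. Real evaluations are *correlated* — physicochemical criteria tend to
be co-missing, and reporting gaps cluster within a study — which independent
sampling deliberately ignores: passing property tests demonstrates the
arithmetic and rendering invariants, not realism of any simulated
literature. `perturb` applies random single-step upgrades (NF→PF, PF→F) and
reports how many were actually applied, to exercise score monotonicity
end-to-end.

## Rendering

Colour maps are fixed by rating (quality: F green, PF yellow, NF red, ND
grey; relevance: DR green, IR yellow, NR red, ND grey) and overridable via a
token→hex mapping. NR's red is an extension by symmetry with the quality
scale — the published relevance chart defines green and yellow only because
no NR occurred — and is declared in the legend like every other colour used.
CSV output carries rating tokens (byte-deterministic for identical inputs);
HTML and SVG carry colours plus a legend restricted to tokens actually
present. Per-study reports contain the bank version, problem formulation,
RQ/MQ scores with section breakdowns, the relevance profile, every
judgement with comments and rationales verbatim, and the removed-criteria
list with reasons; an incomplete evaluation is rejected rather than
partially reported.

## Numerical and procedural choices

- Criterion wording is normalized to straight quotes and single internal
  spaces; equality checks are exact after normalization.
- Rating-matrix CSVs: UTF-8, comma-separated, header row of study ids,
  first column `criterion_id` with `RQ5`-style labels — a one-to-one mirror
  of the printed grids. Token, duplicate-row/column and raggedness errors
  cite the row and study column.
- Bank files are YAML (canonical) or JSON (mirror); loaders validate the
  schema by hand and name the offending location. Round trips are
  structural identities.
- Distribution probabilities must sum to 1 within 1e-9; score comparisons in
  tests use exact or 1e-12-tolerance arithmetic (the computation is a single
  weighted mean, so no looser tolerance is needed).
- Problem sizes in the test suite and acceptance script (1,000 random
  ≤10-criterion evaluations for the oracle/property checks; 180 synthetic
  studies ≈ 10,260 cells for the frequency-convergence check) keep every
  check deterministic and fast while leaving no realistic failure mode
  unsampled.

## Limitations

- Single evaluator per evaluation set; consensus building and inter-rater
  statistics are out of scope.
- The 1.0 criterion texts are not shipped; 1.0-keyed evaluations are
  id-addressed only.
- No weight-of-evidence integration across studies into hazard conclusions,
  and no uncertainty quantification over ratings: the package stops where
  expert judgement and the assessment context take over.
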