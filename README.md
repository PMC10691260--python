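# scirapnano

Structured reliability and relevance evaluation of *in vitro* nanotoxicity
studies, implementing the SciRAPnano criteria-based approach.

Regulatory hazard and risk assessment of nanomaterials (NMs) has to reuse
published *in vitro* toxicity data, but those studies vary enormously in how
well the tested nanomaterial is characterized and how soundly the assays are
run. SciRAPnano extends the SciRAP (Science in Risk Assessment and Policy)
*in vitro* tool with nanomaterial-specific criteria so that an assessor can
appraise each study against a fixed checklist instead of ad-hoc judgement.
This package is aimed at risk assessors and nanosafety researchers who want
that appraisal to be scriptable, validated and reproducible.

## The method

A study is evaluated against a versioned **criteria bank** with three parts:

- **Reporting quality (RQ)** — 38 criteria in tool version 2.0: is each
  design/conduct/analysis element *described*? This includes the 11 key
  physicochemical parameters (size, size distribution, crystallinity, shape,
  surface chemistry, surface charge, surface area, solubility/dissolution
  rate, agglomeration/aggregation, …) plus sample preparation, dispersion
  stability, transformation, interference measures, cellular uptake and dose
  metrics.
- **Methodological quality (MQ)** — 19 criteria: is the design and conduct
  *sound* (dispersion preparation, dispersant interference, NM interference
  with the assay read-out, controls, replicates, statistics, …)?
- **Relevance** — 4 items judged against a stated problem formulation.

Each RQ/MQ criterion is rated on the closed vocabulary
F / PF / NF / ND (fulfilled, partially fulfilled, not fulfilled, not
determined); relevance items use DR / IR / NR / ND (directly / indirectly /
not relevant, not determined). Reliability is summarized per part as a
weighted fulfilment percentage

```
score = 100 · (n_F·w_F + n_PF·w_PF + n_NF·w_NF) / denominator,
w_F = 1, w_PF = 0.5, w_NF = 0 (defaults)
```

where ND ratings are excluded from the denominator by default and criteria
removed for inapplicability (e.g. cell-passage criteria for a study not done
in a cell line) never count. Relevance is deliberately **never** scored
numerically — it is rendered as a qualitative colour profile (green = DR,
yellow = IR, red = NR, grey = ND), mirroring the colour convention of the
quality charts (green = F, yellow = PF, red = NF, grey = ND).

The package also ships the published 11-study titanium-dioxide (TiO₂) case
study — the complete RQ/MQ/relevance rating matrices against tool version
1.0 — as a first-class fixture, plus a seeded synthetic-evaluation generator
for property testing.

## Worked example

```python
from scirapnano import (load_case_study_fixture, quality_score,
                        zero_fulfilled, relevance_profile)

fixture = load_case_study_fixture()          # 11 TiO2 studies, bank 1.0-skeleton
res = quality_score(fixture.get("Study 1"), "RQ")
print("RQ score:", res.rounded(1), res.counts)
for section, s in res.per_section.items():
    print(f"  {section}: {s:.1f}")
print("never fulfilled RQ:", sorted(zero_fulfilled(fixture, "RQ")))
_, counts = relevance_profile(fixture)
print("relevance counts:", counts)
```

prints

```
RQ score: 83.3 {'F': 27, 'NF': 5, 'PF': 1, 'ND': 0}
  Test item and controls: 100.0
  Physicochemical properties of the test item: 63.6
  Test System: 78.6
  Administration of test compound: 100.0
  Data collection and analysis: 100.0
  Funding and competing interests: 100.0
never fulfilled RQ: [12, 13, 18]
relevance counts: {1: {'DR': 11}, 2: {'DR': 8, 'IR': 3}, 3: {'DR': 11}, 4: {'DR': 8, 'IR': 3}}
```

Study 1 reports 27 of its 33 applicable criteria fully and scores 83.3/100
for reporting quality, but its physicochemical characterization section is
the weakest (63.6). Across all 11 studies, water solubility (#12),
dissolution rate (#13) and metabolic competence of the test system (#18)
were never fulfilled, while the identity of the test item and the endpoint
studied (relevance items 1 and 3) were directly relevant everywhere.

A CLI mirrors the library:

```bash
scirapnano bank show --version 2.0 --part RQ --flag new_nm_specific
scirapnano template --bank 2.0 --study-id S1 --not-cell-line --out s1.json
scirapnano score s1.json --part MQ
scirapnano matrix set.json --part RQ --format html --out rq.html
scirapnano synth --bank 2.0 --n 11 --dist F=0.6,PF=0.2,NF=0.15,ND=0.05 --seed 42 --out set.json
```

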