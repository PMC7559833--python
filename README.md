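# panelval

Content validation of questionnaires by expert panels: discordant-judge
screening, Aiken's V with score-method confidence intervals, and
item-validity reporting.

## The problem

Before a new questionnaire is fielded, its items are usually judged by a
small panel of subject-matter experts, each rating every item's relevance on
a bounded Likert scale (here 1–5, with 5 the highest relevance). Two
questions then arise:

1. **Is any judge discordant?** A rater whose answers sit far from the rest
   of the panel on several items dilutes the consensus and should be
   replaced before validity is assessed.
2. **Is each item valid?** Agreement on an item must be quantified, with
   uncertainty, and compared against a pre-set threshold.

`panelval` implements the standard pipeline for both steps and ships, as
embedded fixtures, the two reference panels (11 sports-medicine physicians
and 11 nurses, 30 items each) of a published validation study of a
physical-activity-on-prescription questionnaire, which the test suite
reproduces row by row.

## The statistics

**Screening.** For expert *i* and item *j*, compare the rating `r_ij` with
the leave-one-out mean of the other experts in the screening pool. An
answer is *deviant* when `|r_ij − mean_others| ≥ d` (default `d = 3` scale
points); an expert with deviant answers on `m ≥ 2` items is excluded and
substituted by a replacement judge.

**Aiken's V.** For `n` judges on a scale `l..h` with span `k = h − l`:

    S = Σ_i (r_i − l),    V = S / (n·k)  ∈ [0, 1]

**Score (Wilson-type) 95% interval.** Treating `S` as a score out of `n·k`
effective trials:

    L, U = [2nkV + z² ∓ z·√(4nkV(1−V) + z²)] / [2(nk + z²)],   z = 1.96

Both endpoints satisfy `(V − p)² = z²·p(1−p)/(nk)`. An item is **valid**
when its unrounded `V ≥ 0.75`.

## Worked example

```python
from panelval import ContentValidityModel

results = ContentValidityModel.from_fixture("physicians").fit()
print(results.screening.excluded_experts)   # ('3',)
print(results.summary())
```

The screen excludes expert 3 (four deviant answers, on items 12, 15, 27 and
28); the final panel is the nine retained originals plus replacement expert
11. The summary table starts:

```
Item    1   2   3   4   5   Mean    Aiken's V (95% CI)
1       0   0   0   2   8   4.80    0.95 (0.83-0.98)
2       0   1   0   3   6   4.40    0.85 (0.70-0.92)
```

Item 1 was rated 4 by two judges and 5 by eight, giving a mean of 4.80 and
`V = 38/40 = 0.95` with score interval (0.83, 0.98) — the item is valid.
The table's last lines report the questionnaire-level summary
(`0.84 (SD ± 0.04)` for this panel: mean and SD of the 30 per-item V
values) and the panel descriptives (`28.4 ± 5.1 y` career experience).
V and CI columns are truncated at 2 decimals for display parity with the
classic desk implementation; all comparisons use full precision.

The same pipeline runs from the shell:

```bash
panelval run --fixture nurses --variant table6-reconciled --out-json report.json
panelval run --ratings mypanel.csv --scale 1:5 --pool 1,2,3,4,5,6,7,8,9,10 --replacements 11
panelval simulate --experts 10 --items 30 --deviants 1 --p-dev 0.3 --seed 42 --out sim.csv
```

Exit codes: 0 all items valid, 3 at least one invalid item, 4 load error,
5 configuration error.

## Synthetic panels

`panelval.simulate` generates high-agreement panels
(`r_ij = clamp(round(μ_j + ε))`, Gaussian ε) with optional injected
discordant experts, and `screening_operating_characteristics` estimates the
screening rule's sensitivity and specificity by seeded Monte-Carlo — so
every pipeline stage is testable without external data.

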