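# Methods

## Procedure

The pipeline reproduces the expert-panel content-validation workflow for
Likert-rated questionnaires:

1. **Load** a complete experts × items integer rating matrix on a declared
   scale `l..h`. Missing cells are a load error, never imputed — the
   procedure below is defined only for complete panels, and an incomplete
   panel signals a data-collection problem that should not be hidden.
2. **Screen** the pool of original judges. For expert *i* and item *j* the
   leave-one-out mean `m_ij` is the arithmetic mean of the other pool
   members' ratings at *j*. An answer is deviant when
   `|r_ij − m_ij| ≥ d`; an expert with at least `m` deviant answers is
   excluded. Ties are not broken: every expert meeting the criterion is
   excluded.
3. **Assemble** the final panel: retained originals, in input order, plus
   the supplied replacement judges appended in the given order.
4. **Analyze** each item over the final panel: category frequencies, mean
   rating, Aiken's V, a score-method confidence interval, and the validity
   decision `V ≥ V₀` on unrounded V.
5. **Summarize**: mean, sample SD, min and max of the per-item V values,
   and an overall all-items-valid verdict.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `l`, `h` | 1, 5 | scale categories | Likert bounds; span `k = h − l` |
| `d` (`deviance_threshold`) | 3 | rating points | leave-one-out distance that makes an answer deviant |
| `m` (`min_flagged_items`) | 2 | items | deviant answers that exclude an expert |
| `V₀` (`v_threshold`) | 0.75 | — | minimum unrounded V for item validity |
| confidence | 0.95 | — | score-interval level |
| `z` | 1.96 | — | normal quantile; fixed at 1.96 (not 1.95996…) at 95% for parity with the classic desk implementation, configurable otherwise via `scipy.stats.norm.ppf` |

### The deviance rule

The reference study words its rule ambiguously ("≥3 ± SD different from the
mean of the other 9 experts"). Two readings were implemented:

- `absolute_points` (default): `|r − m_loo| ≥ d` in raw scale points.
- `sd_multiple`: `|r − m_loo| ≥ d · SD_loo` (leave-one-out sample SD).

The absolute-points reading is the default because it reproduces exactly
the deviant cells marked in the published rating tables (four cells for the
physicians' expert 3, two for the nurses' expert 7, single unsanctioned
flags for nurses experts 1 and 8). The SD-multiple reading floods the
panels with flags — any lone dissent from a unanimous item has infinite
SD-distance — and would exclude several experts the study retained; it is
kept only as an explicit sensitivity option and the test suite pins down
its disagreement as a negative control.

The comparison is inclusive (`≥`): a difference of exactly 3.0 points flags
(one such cell exists in the nurses panel; with a single flag that expert
is retained either way, so the fixtures cannot discriminate, and the
inclusive reading matches the rule as stated).

The default screening pool is the ten *original* judges, with the
replacement judge joining only at panel assembly — this matches "the mean
of the other 9 experts". Screening within all eleven raters reproduces the
same flags on both reference panels; the pool is an explicit argument so
either convention can be run.

## Statistics

Aiken's V is the mean rating rescaled to [0, 1]: `V = Σ(r_i − l)/(n·k)`.
The confidence interval inverts the normal score test for a proportion on
`n·k` effective trials:

    L, U = [2nkV + z² ∓ z·√(4nkV(1−V) + z²)] / [2(nk + z²)]

Both endpoints satisfy `(V − p)² = z² p(1−p)/(nk)` (checked to 1e−9 in the
tests); the interval collapses exactly to {0} at V=0 and {1} at V=1, and
narrows monotonically as `n·k` grows.

### Rounding

All statistics are computed, stored and compared at full floating
precision; rounding is purely a display concern. Two print conventions
coexist in the reference report and both are provided: **truncate**
(toward zero — what the classic V/CI desk software prints: 0.9294 → 0.92,
0.975 → 0.97) and **half-up** (descriptives: 11.757 → 11.8). The report
layer defaults to truncate for V/CI columns and half-up for means. Both are
implemented in decimal arithmetic on `repr(float)` so that e.g. 0.89
truncates to 0.89 rather than 0.88 via binary representation error.
Validity is always decided on unrounded V: a V of 0.7499 that prints as
"0.75" fails.

## Embedded reference panels

Both published 11 × 30 rating tables ship as in-package fixtures
(`load_fixture`), transcribed verbatim, together with the published expert
profiles (the excluded judge's profile was not published, so each panel
carries ten profiles). The published tables are internally inconsistent at
a few cells; the raw rating tables are treated as the data authority:

- Nurses, expert 3/item 26 and expert 8/item 27: the ratings print 2 and 1,
  but the published frequency table implies 3 at both cells. Both readings
  are exposed (`variant="verbatim"` / `"table6-reconciled"`), and neither
  is silently preferred. Under the verbatim reading item 27's V is 0.725 —
  below threshold — so the panel's all-valid verdict holds only under the
  reconciled reading.
- Two published frequency rows are internally impossible (they do not sum
  to the panel size); the unique counts consistent with the published
  means — which the ratings produce — are used as test expectations.
- One published frequency row (physicians item 26) disagrees with the raw
  ratings while agreeing on every derived statistic; the ratings win.

## Synthetic panels

The generator emulates the study regime: `r_ij = clamp(round(μ_j + ε_ij))`
with `ε_ij ~ N(0, σ)` i.i.d.; a deviant expert's answer is replaced, with
per-item probability `p_dev`, by `clamp(round(μ_j − δ))`. Defaults are the
study design point: 10 experts, 30 items, 1–5 scale, `μ_j ~ U(4, 5)` (a
high-agreement questionnaire, matching the fixture regime where every
published item validates), `σ = 0.5` (most ratings within one point of
consensus), `δ = 3`, `p_dev = 0.3`. Gaussian noise is the simplest
symmetric choice; the contract is distributional shape plus σ, not a
specific family. Deviance is low-ball (subtracts δ) because every marked
deviant cell in the reference tables is a rating of 1 under a high
consensus; rounding of the latent value is half-to-even, which is
measure-zero-irrelevant for σ > 0.

Draw order (item means, noise, deviant identities, deviance mask) is part
of the generator's contract: under a common seed, raising `p_dev` only adds
deviant cells and raising `δ` only pushes deviant ratings further down, so
the screening rule's sensitivity is pathwise monotone in both — the test
suite exercises this directly rather than relying on noisy estimates.
Replicate *r* of the operating-characteristics harness uses seed
`master + r`, so enlarging the replicate count never perturbs earlier
draws.

What the generator does **not** emulate: per-expert severity/leniency
offsets, item-by-expert interactions, ordinal response styles
(end-aversion, central tendency), or correlated items. Passing recovery
tests therefore shows the screening rule behaves as designed under clean
high-agreement noise, not that it is robust to structured rater effects.

A deliberately informative consequence of the design point: a deviant
answer `round(4.5 − 3) = 2` sits only ≈2.5 points from a ≈4.5 consensus,
*below* the 3-point threshold, so at `δ = 3` the rule's sensitivity is
essentially zero (flags require all nine other judges at 5) while at
`δ = 4` — deviant answers at the scale floor — it is essentially one. The
operating-characteristics tests assert agreement with a pre-registered
brute-force Monte-Carlo oracle at 500 replicates within the binomial 95%
bound, and the null configuration (no deviants, σ = 0.5) keeps the
false-exclusion probability at zero, far inside the 5% calibration bound.

## Problem sizes and determinism

The test suite runs the two 11 × 30 reference panels end to end
(milliseconds), property checks on ~1,000 random panels, exhaustive
screening equivalence against a first-principles brute force on all tiny
3-category panels, and 500-replicate Monte-Carlo for the operating
characteristics; the whole suite completes in well under a minute.
`run_validation` is deterministic: identical config and input produce
byte-identical JSON/CSV reports (report provenance deliberately carries no
timestamp).

## Known limitations

- Single scale per matrix: items with heterogeneous category counts are out
  of scope.
- Screening is one-pass: the panel is not re-screened after exclusion
  (matching the reference procedure); replacements are supplied data, not
  recruited by the package.
- The score interval is the only interval offered (no Bayesian or
  exact-binomial alternative), and experts are unweighted.
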