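# Methods

## Design being analysed

A parallel-group trial with participants randomized 1:1:1 to three arms —
do-nothing, attention placebo control (APC; a video matched on format and
duration but without the health-message content), and the intervention
video — and, within every arm, randomized 1:1 once to either the control
list or the treatment list for all five nested list experiments. This
yields a six-cell (arm × list) design. The APC lets the total effect of the
intervention (intervention − do-nothing) be decomposed into an attention
effect (APC − do-nothing; the effect of watching any video) and a content
effect (intervention − APC; the message itself); the three contrasts
satisfy `content + attention = total` as an algebraic identity, which the
implementation preserves exactly by deriving all three from one model.

## Knowledge endpoint

Score = number of correct answers over 18 true/false items (range 0–18).
Each item has a 30-second limit; a timed-out item is carried in the data as
a distinct code (9) and recoded to incorrect at scoring time — keeping the
recode an explicit, testable step rather than a property of the file
format. Analysis is complete-case only: participants who did not finish the
survey are dropped (no imputation), with the counts logged.

Between-arm inference is a one-way ANOVA plus Tukey HSD pairwise
comparisons. Unequal arm sizes are handled with the Tukey–Kramer
(harmonic-mean) allowance via the studentized range distribution. Arm-mean
95% CIs use the normal approximation `mean ± z·SE`; at thousands of
participants per arm the t/normal distinction is far below reporting
precision.

Because scores sit near the ceiling, each contrast is also reported
relative to its headroom, `18 − comparator mean` (comparator = do-nothing
for the total and attention effects, APC for the content effect). The
relative gains are full-precision ratios of the computed quantities. Note
that ratios of *rounded* published summaries need not reproduce published
percentages: 0.09/1.14 = 7.9%, not the 7.6% a summary computed from
unrounded means can give. The package never adjusts its output to match
such rounded presentations.

Reliability is split-half: Pearson correlation between odd-item and
even-item half scores. The odd/even split is a choice (any split-half
statistic requires one); both the raw coefficient and the Spearman–Brown
step-up 2r/(1+r) are reported because "split-half coefficient" is ambiguous
between them. Zero variance in a half raises an error rather than silently
reporting 0.

## List-experiment endpoint

For experiment *i* and arm *k*, with treatment-list mean count T̄ and
control-list mean C̄, the prevalence of the sensitive behavior is
`(T̄ − C̄) × 100` percentage points, with
`SE = 100·sqrt(s²_C/n_C + s²_T/n_T)` and a normal CI. This identifies the
prevalence under the item-count technique's two assumptions: *no design
effect* (adding the sensitive item does not change responses to the control
items) and *no liars* (truthful counts). Negative estimates are reported
as-is; truncation would bias the arm contrasts.

Arm contrasts are estimated by OLS. For a pair of arms the model is the
saturated 2×2 regression `y = b0 + b1·VideoArm + b2·TreatList +
b3·(VideoArm×TreatList)`; b3 is then *identically* the cell-mean
difference-in-difference, which the test suite verifies to 1e-10 on
arbitrary data — the strongest available oracle for the fit. For the
three-arm decomposition a single joint OLS with two arm dummies (reference:
do-nothing) and full interactions is used, so total/attention/content are
linear combinations of coefficients within one covariance matrix and the
decomposition identity holds exactly. Pairwise fits are also exposed and
agree with the joint fit's point estimates (saturation). A two-arm model
with a single arm indicator cannot represent three arms; the joint
parameterization is the natural generalization.

Standard errors are classical homoskedastic, p-values two-sided from the t
distribution on the residual df (at trial scale, t vs normal is
negligible). A heteroskedasticity-robust option was deliberately left out
of the default path: count variances across the six cells are close to
equal under the generator, and the bootstrap check in the test suite shows
the classical SEs are accurate to within a few percent there. Prevalences
are conventionally read at one decimal in percentage points; effects at
three decimals on the proportion scale.

## Synthetic-trial generator

What it emulates, and the defaults (the study conditions):

- **Cells.** Exactly `n_per_cell` records per arm × list cell (default
  2,400, ≈14,400 enrolled — the scale of the real trial).
- **Knowledge.** Item *j* in arm *k* times out with probability
  `timeout_rate` (default 0.01, a realistic low rate for a 30-second
  window; the real rate is unpublished) and is otherwise correct with
  probability `knowledge_p[k][j]`. The default per-item profile has one
  ~99% item and a gradually harder tail, scaled so expected scores are
  16.86 / 16.89 / 16.95 (do-nothing / APC / intervention) — the published
  arm means — implying a 93.7% do-nothing correct-response rate.
- **List counts.** Control-list count = sum of 5 independent Bernoulli
  endorsements with per-item probabilities `control_item_p[i]` (experiment 1
  defaults sum to 2.03, the published control mean; others sit near 2.0).
  Treatment-list count = the same draw process plus an independent
  Bernoulli endorsement of the sensitive item with probability
  `sensitive_prevalence[arm][i]` — the no-design-effect assumption built
  in. Experiment 1 defaults are the published prevalences (21.7% / 29.4% /
  17.2%); experiments 2–5 have no published point estimates, so the
  defaults encode the reported qualitative pattern (high hygiene-behavior
  intent, a positive intervention shift for dish-cleaning, reduced
  stockpiling intent) and are documented, frozen choices.
- **`design_violation`** adds a constant to the control-item probabilities
  on treatment lists only, to study estimator bias when the identifying
  assumption fails (default 0).
- **`item_correlation`** optionally couples the five control items through
  a Gaussian copula with an equicorrelated latent propensity; marginal
  endorsement probabilities are preserved. Default 0 (independence, the
  minimal assumption — the estimator's validity does not require more).
- **Demographics** are drawn from frozen marginal frequencies (counts over
  the 14,482-completer reference margins: UK 58.8%, US 26.0%, English first
  language 84.9%, ≥ some college 81.6%, ...). They are cosmetic — they feed
  only balance tables — so independent marginals suffice and no joint
  distribution is modeled.
- **Attrition**: `completed=false` independently with probability 0.033
  (the post-randomization loss fraction implied by the trial's flow
  counts); analysis stages filter to completers.
- **RNG**: one root seed split into six per-cell substreams in fixed order,
  so output is byte-identical for a fixed config.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: inter-item correlation in knowledge responses
(defaults give near-zero split-half reliability, unlike the ~0.65 of a real
questionnaire; switch on `item_correlation`-style structure only for the
list items), response-time behavior, item-wording effects, country-level
heterogeneity in prevalence, and any correlation between demographics and
outcomes. Second moments of the real list counts are unpublished, so the
generator is calibrated to the published means only.

## Numerical and design choices

- Cell means/variances use sample variances (ddof = 1); empty design cells
  raise a named contract error rather than producing NaNs.
- A zero-weight linear combination returns estimate 0, SE 0 and an
  undefined (NaN) p-value — not p = 1.
- The balance table's test is the chi-square test of independence of each
  demographic against the six arm × list cells (the conventional
  randomization check for categorical baselines; the original analysis
  software's exact test is unknown, so exact reproduction of published
  balance p-values is not claimed).
- Trial flow counts in the source publication are internally inconsistent
  at the ±17 level; the schema takes the completion flag as given and does
  not attempt to reconcile enrollment arithmetic.
- Published worked-example arithmetic mixes rounded display values with
  unrounded computation (cell means printed at 2 dp determine a prevalence
  only to ±1.0 pp). The implementation always computes from full-precision
  inputs; tests compare to published numbers only at the precision the
  published inputs support.

## Problem sizes used in the checks

The identity and small-sample checks run on datasets of 2–200 per cell; the
parameter-recovery check uses 50,000 per cell (difference-in-means SE ≈ 0.7
pp, so the configured prevalences are resolved well within 3 SE); the
type-I-error check uses 1,000 simulated trials at the study's own cell size
of 2,400, giving a 3σ binomial band of 5% ± 1.7 pp for the rejection rate.

## Known limitations

- Estimators are difference-in-means/OLS only; no maximum-likelihood or
  covariate-adjusted list-experiment estimators, and no design-effect or
  liar-detection diagnostics beyond the generator's violation knob.
- No item-response-theory modeling of the knowledge scale; no
  covariate-adjusted ANOVA.
- Complete-case analysis only; informative attrition would bias both
  endpoints and is neither modeled nor corrected.
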