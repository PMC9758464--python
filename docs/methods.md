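# Methods

This document records the models and estimation choices the package
implements. It describes *how* quantities are computed; numerical results
appear only in artifacts the pipeline itself writes.

## Design generation

Sixty topics are partitioned into four fixed sets (1–15, 16–30, 31–45,
46–60) and rotated through the four headline-type conditions by a Latin
square over the counterbalance index, so that across the four lists every
topic serves every condition exactly once. Phase orders are drawn by
rejection sampling with local swap repair (bounded at 10,000 restarts) until
two constraints hold in every phase: no more than three consecutive topics
from the same condition, and every condition's mean list position within 2.0
of the grand mean (30.5 for 60 items). Phase-2 fake-news reminders share the
list position of the correction they precede. All generation is
deterministic given a seed.

## Generative model of trials

Each participant p and topic i carry shared logit-scale random intercepts
u_p ~ N(0, sd_participant²) and w_i ~ N(0, sd_item²). On a correction trial
in condition c, a recollection indicator is drawn with probability
invlogit(logit(r_c) + u_p + w_i); if it fails, a familiarity indicator with
probability invlogit(logit(f_c) + u_p + w_i) decides between an intrusion
and an "other" response. Correction classification depends on recollection
(p_classify_given_recollect vs p_classify_given_no_recollect), and fake
recall is only possible after a "yes" classification. Repetition trials use
p_repetition_recall on the same logit scale. Belief ratings are a latent
Normal — mean set by response type and condition, plus a participant belief
intercept — thresholded at cutpoints 1.5, …, 5.5 into 1–6 ratings.

Calibration convention: all generating probabilities are *conditional*
(random effects at zero), so the GLMM's inverse-link fixed-effect estimate
and the MPT's invlogit(μ) are the quantities the generator pins down. The
default calibration's condition differences equal the published difference
estimates the acceptance suite targets; the absolute anchors are design
choices respecting the qualitative ordering of recall and intrusion rates.

## Response coding

Every trial is coded REAL_RECALL, INTRUSION, or OTHER; repetition trials can
never yield INTRUSION (no fake counterpart exists). Correction trials are
further classed by the classification judgment crossed with fake recall:
CORR_FN_RECALLED, CORR_FN_NOT_RECALLED, NOTCORR_FN_NOT_RECALLED. On
synthetic data the intrusion flag is an explicit generator column; scored
real data may instead supply a precoded `response_category` column.

## Mixed-effects models

Binary outcomes use logistic mixed models with crossed participant and item
random intercepts; belief ratings use Gaussian linear mixed models with the
same random structure. Fitting is delegated to R's lme4 through an
`Rscript` subprocess exchanging CSV/JSON: `glmer` (Laplace approximation,
bobyqa optimizer) for binomial models and `lmerTest::lmer` (REML) for
Gaussian models, always in the cell-means parameterization
`y ~ 0 + cell + (1|participant) + (1|item)`. This backend was chosen after
the pure-Python alternative (statsmodels' Bayesian mixed GLM) proved
unreliable for the condition-by-classification interaction models: its MAP
optimizer diverges (variance components collapse without bound) and its
variational approximation materially under-covers the fixed effects.

Reported per-level estimates are conditional (random-effects-at-zero):
the inverse link of the fixed-effect coefficient, with Wald 95% intervals on
the link scale. All-pairs contrasts are Wald z statistics for logistic
models and t statistics with per-contrast Satterthwaite degrees of freedom
(via `lmerTest::contest1D`) for Gaussian models; the degrees-of-freedom
method is recorded in the fit's convergence metadata. Multiplicity
adjustment defaults to Tukey (studentized-range), with Holm and unadjusted
options. Factor-level tests are Wald chi-square tests built from contrast
matrices over the cell means, weighting observed cells equally; interaction
contrasts over incomplete 2×2 subtables are skipped. Complete separation
(a constant outcome within a cell) is detected before fitting and raised;
lme4 non-convergence raises with diagnostics attached, and singular
(zero-variance) fits are reported but not treated as failures.

The conditional models cross headline type with classification class. For
the intrusion outcome the CORR_FN_RECALLED class is excluded (intrusions
there are redundant with fake recall and sparse), and any cell under the
`min_cell` threshold is flagged and omitted from the fit.

## Hierarchical multinomial processing tree

The adopted tree is just-identified per condition: P(real) = r,
P(intrusion) = (1−r)f, P(other) = (1−r)(1−f), with a closed-form moment
inverse (r̂ = n_real/n, f̂ = n_intrusion/(n − n_real)) used as an
independent oracle.

The hierarchical model places one standard-normal latent ability x_pc on
each participant-by-condition cell, entering both parameters with
parameter-specific loadings:

    η_r = μ_r[c] + σ_r · x_pc        η_f = μ_f[c] + σ_f · x_pc

Two deliberate choices here, both documented deviations from the simplest
"one effect per parameter shared across conditions" hierarchy:

1. **Per-condition cells.** With effects shared across conditions,
   participant effects cancel in condition contrasts and the contrast
   credible intervals become implausibly narrow relative to the published
   interval widths the calibration targets; per-condition cells restore
   realistic contrast uncertainty.
2. **A shared ability per cell rather than independent δ_r, δ_f.** The
   familiarity branch is only observed when recollection fails, so when the
   generator couples the branches through a shared participant effect,
   independent per-parameter effects produce a selection bias in f for
   high-recollection conditions. The shared-cell-ability model removes this
   bias in recovery studies while keeping contrast widths at the published
   magnitude.

The cell ability is marginalized by 31-node Gauss–Hermite quadrature, so the
sampled parameter vector holds only μ_r[c], μ_f[c], log σ_r, log σ_f.
Priors: μ ~ N(0, 1.5²) (near-uniform on the probability scale),
σ ~ Half-Normal(1) sampled on the log scale with the Jacobian correction.

Sampling uses the emcee affine-invariant ensemble sampler (the environment
provides no pymc/numpyro): 4 independent 16-walker ensembles, 1000 steps
with the first 500 discarded, each ensemble treated as one chain for
arviz split-R̂ and effective-sample-size diagnostics. The fit raises when
split-R̂ exceeds 1.05. Initialization is at pooled moment estimates plus
small seeded jitter; fits are byte-reproducible under fixed settings.

**Known limitation — absolute levels vs differences.** The tree is fit to
per-participant counts, so item (topic) variability in the generative
process is invisible to it: the realized item sets shift a dataset's
conditional probabilities jointly across conditions, which the credible
intervals for the *absolute* r and f levels cannot reflect. In recovery
studies this appears as essentially zero bias but mild under-coverage of
the absolute levels, with interval misses co-occurring across parameters
within a replicate; low-count familiarity cells (familiarity is only
observed when recollection fails) show some residual excess dispersion as
well. Condition *differences* — the quantities the analyses report — are
unaffected, because the common dataset-level shift cancels in draw-wise
contrasts. A trial-level tree with crossed item random effects would
address this at the cost of losing independence across participants; it is
out of scope here.

Population estimates are posterior summaries of invlogit(μ) — the
median-participant convention matching the GLMM's conditional estimates.
"Credible" means the central 95% interval of a probability-scale draw-wise
difference excludes zero. Per-participant empirical-Bayes cell effects are
reported at the posterior mean of the group-level parameters. The
`recover` harness re-simulates and refits to report bias, RMSE, and interval
coverage per parameter.

## Pipeline and provenance

`run_pipeline` executes seven stages in the order of the result narrative —
overall recall, intrusions, fake recall, conditional models, MPT, beliefs,
conditional beliefs — isolating stage failures so later independent stages
still run. Every run writes a manifest with the config hash, the master
seed and derived per-stage seeds, and library versions; deterministic stages
reproduce identical artifact digests under identical provenance. Tables
use a conventional (analysis, effect, statistic, df, p) results layout,
and figure summaries are tidy CSVs whose cell
proportions sum to one within each conditioning family.
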