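# Methods

## The prediction problem

The unit of analysis is the index patient (proband): a CRC patient whose
tumour was screened for Lynch syndrome on behalf of their family. The
outcome is five-category mutation status — no MMR mutation, or a germline
mutation in *MLH1*, *MSH2*, *MSH6* or *PMS2*. Inputs are the proband's
personal tumour history (number of CRCs, age at first CRC, tumour side,
endometrial cancer, other LS-associated tumours) and summary family
history: counts and youngest ages at diagnosis of CRC, endometrial cancer
and other LS tumours among first- and second-degree relatives. This
one-row-per-proband granularity matches what the linear-predictor risk
models consume; full pedigrees (as Mendelian-likelihood models require)
are deliberately out of scope.

## Risk models

Both model shapes are *configured*, not hard-coded: a coefficient file
names its outcomes, per-outcome intercepts and coefficients, and an
encoding recipe per covariate (indicator, count capped at a maximum, or
shifted/scaled age with an optional default for structurally absent
values). A covariate the recipe needs but the patient cannot supply is an
error — unknown history is never silently imputed as negative.

* Multinomial (four-gene): p_g = exp(lp_g) / (1 + Σ_h exp(lp_h)),
  p_none = 1 / (1 + Σ_h exp(lp_h)). Computed with a max-shifted softmax,
  stable for |lp| up to ~700; probabilities always sum to 1 within 1e-12.
* Logistic (CRC-proband): p = expit(lp); raises a not-applicable error for
  probands without CRC.

The shipped configs reproduce the *structure* of the published models
(which covariates enter, how they are encoded, which model carries tumour
side) but with synthetic numeric values, clearly labelled in the files:
the published equations are not printed in the source material available
here, and inventing unlabelled numbers would be worse than shipping
labelled stand-ins. Every quantitative test in the package therefore uses
toy coefficient sets or synthetic-data fits.

## Revised Bethesda classification

Criteria evaluated from the schema: C1 CRC < 50; C2 synchronous or
metachronous CRC or another LS tumour in the proband; C4 CRC plus a
first-degree relative with an LS tumour < 50 (only relatives' CRC and EC
carry ages in the schema, so only they can satisfy the age clause); C5 CRC
plus ≥ 2 first- or second-degree relatives with LS tumours at any age. Age
comparisons are strict. C3 (MSI-high histology < 60) needs tumour data the
cohort schema does not carry; it is reported as not evaluable and excluded
from the fulfilment disjunction rather than treated as false. How the
original analyses handled C3 is not documented; this treatment is this
package's own choice.

## Model updating

Updating keeps the multinomial structure and refits only a small parameter
set on new data:

    LP_g = α_g + β_g·lp_g [+ γ_g·proximal] (+ δ·I(≥2 CRCs) in MSH6 only)

The constraint — each original predictor feeds only its own gene's
category — is a structural zero in the design, so the likelihood is
concave in (α, β, γ, δ) and is maximized by unconstrained BFGS with an
analytic gradient, starting from the identity update (α=0, β=1, γ=0,
δ=0). Convergence requires gradient max-norm < 1e-6 (absolute, with a
relative fallback scaled by the objective); maximum 500 iterations. Any
parameter beyond ±15 on the logit scale marks the fit non-converged
(separation guard: small cohorts with rare PMS2 outcomes can separate).
Log category probabilities are floored at −700 inside the likelihood.

Design choices where the procedure was genuinely open:

* Adaptation 1 frees {α_g, β_g for all g, δ}; adaptation 2 additionally
  frees {γ_g for all g}. A `fix_beta` switch pins slopes at 1 (pure
  extension) for users who prefer recalibration and extension separated.
* δ *replaces* the original MSH6 two-or-more-CRCs term: that coefficient
  was estimated on development data containing no eligible carriers, so
  the original term is subtracted from lp_MSH6 when the dataset is built
  and δ is estimated fresh.
* The two-category degeneracy (a single gene vs none) reduces exactly to
  binary logistic regression; the test suite exploits this with an
  independent statsmodels oracle (agreement to 1e-4).

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counted 1/2;
the test suite pins it to a brute-force pairwise-concordance oracle on
random instances. Confidence intervals use the DeLong variance estimator
(deterministic, the standard for risk-score AUCs; the source analyses
report 95% CIs without naming a method). Paired AUC differences use the
joint DeLong covariance. Per-gene contrasts take carriers of one gene as
positives and non-mutation carriers as negatives, excluding carriers of
other genes; both the overall and the gene-specific probability are
supported as the score (default overall — which of the two the original
analyses used is not stated, so neither is asserted as "theirs").
Classification at a cut-off uses score ≥ cutoff, matching the ≥ 5%
referral convention; percentages are rounded half-up to whole percent as
in clinical tables.

## Cohort statistics

Frequency rows dispatch to Fisher's exact test when any expected cell
count is below 5 and to Pearson chi-square without continuity correction
otherwise; the test used is recorded per row. Ages are summarized as
median [Q1–Q3] (linear-interpolation quantiles) and compared by
Mann–Whitney U — exact enumeration for tie-free groups smaller than 8,
otherwise the tie-corrected normal approximation. Endometrial-cancer rows
use female denominators only. The 1% significance threshold is reported as
metadata, never used as a filter.

## Synthetic cohort generator

The generator emulates a high-risk clinic cohort of CRC probands: status
drawn from prevalences 651:23:17:31:12 / 734 (≈11.3% carriers, PMS2 ≈14%
of carriers), then covariates from status-conditional laws — Bernoulli for
flags and family-history tail probabilities P(count ≥ 1), P(count ≥ 2),
truncated normals (18–95 or 18–100 years) moment-matched to target
medians/IQRs for ages. The defining feature of the calibration is that
PMS2 carriers resemble non-carriers on everything except tumour side
(proximal 83% vs 28%), while other carriers differ broadly (younger CRC,
endometrial cancer in 47% of carrier women vs 3.2%, more multiple CRCs,
younger affected relatives). Non-PMS2-carrier values were derived by
subtracting the PMS2 column from the all-carrier column where the
published margins allow.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: covariates are conditionally independent given
status (real family history is correlated with proband age and across
relatives), ages are symmetric truncated normals (real onset ages are
skewed), every proband has ≥ 1 CRC, relatives' "other LS tumour" counts
carry no ages, and there is no misreporting or verification bias. Results
on synthetic cohorts demonstrate the *machinery* and the direction of
effects, not clinical performance.

## Problem sizes and numerical defaults

Default analysis cohorts are n = 5000 (demo, acceptance pipeline) —
large enough that the extension's PMS2 improvement (ΔAUC ≈ +0.2) is
stable across seeds — and n = 20 000 for single-draw parameter-recovery
checks. Optimizer: BFGS, gradient tolerance 1e-6, max 500 iterations,
separation bound 15. Probability-normalization tolerance 1e-12. Random
seeds flow through `numpy.random.SeedSequence` spawns so that no two
generators ever share a stream (sharing one raw integer seed between the
covariate generator and an outcome redraw provably correlates them).

## Known limitations

* Shipped coefficient values are synthetic stand-ins; clinical use
  requires transcribing the published equations into the config format.
* The MMRpredict-style model implements only the clinical
  (pre-tumour-testing) stage; MSI/IHC-augmented stages need tumour data
  outside the schema.
* Single-draw recovery of the updating parameters at n = 20 000 has
  Monte-Carlo SEs up to ≈0.22 for the rare-gene intercept (PMS2), so
  individual estimates can sit 0.1–0.3 from truth without any bias;
  replicate averages are the meaningful recovery check.
* Fisher's exact test uses the conventional two-sided hypergeometric tail
  sum; mid-p variants are not offered.
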