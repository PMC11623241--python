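# Methods

## The models

`mdnrm` implements a family of Bayesian item-response models for
*multiclass* observer studies — settings where J raters (radiologists,
pathologists, annotators) each assign one of C nominal classes to each of
I cases whose true class is known. One row of data is a tuple
(case *i*, rater *j*, ground truth *s*, response *r*). All variants share
the softmax (nominal response) likelihood

    Pr(r_ij = t | s) = exp(z_t) / Σ_h exp(z_h),

and differ in the logit `z`:

| variant      | logit `z_ijst`            | θ shape   | α shape | β shape |
|--------------|---------------------------|-----------|---------|---------|
| `nrm_2pl`    | α_it·θ_j + β_it           | (J,)      | (I,C)   | (I,C)   |
| `nrm_1pl`    | θ_j + β_it                | (J,)      | —       | (I,C)   |
| `mdnrm_orig` | θ_jst + β_is              | (J,C,C)   | —       | (I,C)   |
| `mdnrm_a`    | α_is·θ_jst + β_s          | (J,C,C)   | (I,C)   | (C,)    |
| `mdnrm_b`    | α_s·θ_jst + β_is          | (J,C,C)   | (C,)    | (I,C)   |
| `mdnrm_r`    | α_is·θ_jst + β_is         | (J,C,C)   | (I,C)   | (I,C)   |

The multidimensional (MDNRM) variants condition on the ground truth: the
ability parameter of rater *j* is a C×C matrix whose entry (s, t) is the
propensity to answer *t* when the truth is *s*; large diagonal entries mean
an accurate rater. The discrimination α scales how sharply a case separates
raters, and the easiness β is an additive per-case (or per-class) offset.

### The easiness parameter is not identified (by construction)

In all four MDNRM logits the β term carries no response index *t*: within
one (i, j, s) triple it shifts every class logit equally and cancels in the
softmax. The likelihood therefore contains no information about β, and its
posterior must equal its Normal(0, 2) prior. The same cancellation applies
to θ_j in `nrm_1pl`. The package implements the equations exactly as they
stand rather than silently re-indexing them, because the published analysis
was run this way and reproducing it is the point; the property is turned
into an asset:

* `pointwise_loglik` drops the cancelling term before the softmax, so the
  log-likelihood is *bit*-invariant to β — asserted exactly in the tests;
* after any real fit, each β marginal is tested against Normal(0, 2) —
  a sharp end-to-end correctness check of the sampler;
* the recovery report flags β (and θ for `nrm_1pl`) as non-identified
  instead of counting it as a recovery failure.

For users who want an identified easiness, `ModelSpec(...,
beta_response_indexed=True)` re-indexes β by the response class (β_it /
β_t), which does not cancel. It is an extension and is not used when
reproducing the published analysis.

## Priors and their parameterization

* θ and β: Normal(0, 2) per entry.
* α (nonnegative): either Gamma(shape = 2, rate = 2) — mean 1, the
  conventional discrimination scale — or half-normal with scale 10.
  The gamma is parameterized shape/rate (not shape/scale): this matches the
  convention of the probabilistic-programming stacks these models are
  usually written in and gives a weakly-informative prior centred on 1.
* Variants without a discrimination parameter (`mdnrm_orig`, `nrm_1pl`)
  take no α prior; a spec that names one is normalized to `none`.

## Inference

`fit` runs a self-contained No-U-Turn sampler written against the exact
analytic gradient of the log posterior (the softmax gradient
`1[t=r] − p_t` scattered onto the parameter arrays; a numba kernel computes
density + gradient + leapfrog, with an equivalent pure-numpy fallback).
Details that matter:

* α is sampled on the log scale (`u = log α`) with the Jacobian included,
  so the kernel never sees the constraint boundary.
* Chains are initialized independently from the prior. One master seed
  fans out per-chain seeds via `numpy.random.SeedSequence`; identical
  spec + table + config + seed gives bit-identical draws.
* Warmup uses dual averaging toward a target acceptance statistic of 0.8
  plus a diagonal mass matrix re-estimated over doubling windows
  (15% initial fast interval, doubling slow windows, 10% terminal
  interval). Below 100 warmup iterations the mass stays at identity.
* Divergences (energy error > 1000) are counted per chain and carried on
  the result object; they are reported, never dropped.
* Default settings are 8 chains × (1,000 warmup + 8,000 draws), the
  published configuration. Everything in the test-suite and the
  acceptance script runs reduced sizes (2–4 chains, hundreds to a few
  thousand draws per chain), chosen so a study-sized fit takes on the
  order of a minute while split-R̂ still resolves non-convergence; the
  posterior means these sizes give are stable to well within Monte-Carlo
  error of the full-size settings.

Convergence is judged by rank-normalized split-R̂ (pooled draws replaced
by normal scores, chains split in half, classic between/within variance
ratio); the threshold follows the published rule R̂ < 1.10. Plain split-R̂
is available via `rhat_array(..., rank_normalize=False)`. Zero-variance
parameters give NaN with a warning rather than a spurious 1.0.

## Model comparison

Both criteria are computed from the S×N pointwise log-likelihood matrix
and reported on the deviance scale (−2·elpd), which is the scale on which
the published table's magnitudes (~1,000 for 900 three-class responses)
live:

* wAIC: `lppd − p_waic` with `p_waic = Σ_n var_s(ll_sn)` (sample variance,
  denominator S−1).
* PSIS-LOO: per observation, raw importance log-weights `−ll_sn` are
  Pareto-smoothed — a generalized Pareto distribution is fitted to the
  M = min(0.2·S, 3√S) largest weights by the Zhang–Stephens
  empirical-Bayes profile estimator, the tail is replaced by expected
  order statistics of the fit, and weights are truncated at the raw
  maximum. The fitted shape k̂ is reported per observation; values above
  0.7 are counted and warned about. A zero-variance weight vector (e.g.
  a degenerate posterior) falls back to the in-sample `lppd_n` with
  k̂ = NaN and a warning.
* Standard errors are `2·√(N·var_n)` of the pointwise contributions
  (ddof = 1). Rankings use point values; ties break by model label.

The tests pin wAIC to a loop-wise direct-formula oracle at 1e−10 and
PSIS-LOO to the established arviz implementation at 1e−6.

## Posterior comparison

* HDI: shortest contiguous interval over the sorted pooled draws
  (sliding window of ⌈prob·n⌉ draws). Default mass 0.94.
* Probability of direction: max(Pr(>0), Pr(<0)) with exact zeros split
  evenly, so a symmetric sample gives exactly 0.5.
* A contrast between two ability entries is called *significant* when 0
  lies outside the 94% HDI of the pooled-draw difference. The published
  analysis couples PD with a 94% HDI without stating its decision rule
  explicitly; this HDI-excludes-zero rule is the standard existence test
  and reproduces the published verdicts. PD is always reported alongside
  so users can apply their own cutoff; no multiplicity correction is
  applied (deliberately left to the analyst).

## The synthetic-data generator

`generate_dataset` draws case ground truths from a configurable prevalence
(uniform by default), draws parameters from the model priors (unless fixed),
and samples each response from the variant's softmax probabilities. Defaults
mirror the real study's geometry — 6 raters, 150 cases, 3 classes — so
simulated information content matches the real experiment's.

When the simulator draws *truth* discriminations, the package's standard
condition is the Gamma(2, 2) prior (mean 1, the conventional
discrimination scale): simulated raters then misclassify at rates
comparable to real observers. Drawing truths from the half-normal
scale-10 prior instead gives median discriminations near 7 and logits of
order ±13, i.e. almost deterministic raters — a legitimate prior for
*fitting*, where the likelihood pulls α to where the data live, but an
unrealistic *generating* condition (and one whose α·θ posterior ridges
make every fit several times slower). Recovery and convergence
experiments therefore simulate under gamma truths while still fitting
whichever prior configuration is under study.

What it does *not* emulate: correlation between raters beyond the shared
case parameters, case-difficulty drift, reader fatigue, missing responses,
or class prevalences estimated from real cohorts. Passing recovery and
convergence tests on simulated data therefore demonstrates the
correctness and calibration of the implementation under the model's own
assumptions, not the adequacy of the model for any particular clinical
dataset.

`recovery_experiment` redraws generating parameters per replicate,
refits, and reports bias/RMSE of posterior means plus 94%-HDI coverage
per parameter family; for a correctly implemented Bayesian model the
coverage of identified parameters is ≈ 0.94 (the tests accept
[0.88, 0.99] at 20 replicates).

## Numerical choices and degenerate inputs

* Softmax and log-softmax are max-subtracted; `class_probabilities`
  rejects non-finite logits.
* `fit_gpd_tail` requires ≥ 5 sorted positive excesses and rejects
  all-equal input; its weak prior (strength 10, pulling k̂ toward 0.5)
  stabilizes short tails.
* HDI of a point mass collapses to (v, v); `pd` of an all-zero sample is
  0.5 by the even split.
* Comparison of models fitted to different observation counts is an error,
  as is a single-chain R̂ or a single-draw wAIC.

## Reproduction scope

The published dataset (900 responses of 6 radiologists over 150 chest-CT
cases: normal vs non-COVID pneumonia vs COVID-19 pneumonia) is publicly
available but not redistributed here. The reproduction test
(`tests/test_acceptance.py::test_published_study_reproduction`) runs the
full seven-model comparison and the rater-1 vs rater-5 contrast when the
CSV is placed at `data/ground_truth_and_results.csv`, and fails with a
pointer to the source otherwise. All other tests are self-contained via
the simulator.
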