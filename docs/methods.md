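# Methods

## Setting

Two saturation-genome-editing screens of the same region report raw
depletion-type functional scores for largely overlapping sets of SNVs, with
different cell backgrounds, replicate counts (at least three vs two) and
score scales. The package integrates the two score sets into a single
functional call per variant and propagates that call into a points-based
ACMG/AMP classification. Lower scores always mean stronger depletion
(loss of function); this convention is fixed in the generator and used
consistently everywhere downstream.

## Synthetic screens

`SimulationConfig` / `simulate_screen` generate the study conditions all
tests run under. Per variant a latent effect θ_v is drawn from the
component matching its true status; each observation is

    y = b_{e,r} + exp(g_{e,r}) * θ_v + τ * t_ν

with replicate-by-exon location effects b and log-scale effects g (log
scale keeps the multiplicative term positive without truncation), and
Student-t residual noise for outliers. Second-assay observations then pass
through an affine distortion (`assay_offset + assay_scale * y`) emulating
the scale difference between the source screens, and observations drop out
completely at random at `missing_rate` (no missingness mechanism is
modelled beyond that).

Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_variants` | 500 | desk-scale screen; large enough for stable category counts |
| `replicates_per_assay` | A1: 3, A2: 2 | unequal replication of the two source screens |
| `consequence_mix` | syn .18 / non .07 / mis .70 / splice .05 | missense-dominated, as in an exonic SNV scan |
| `frac_missense_pathogenic` | 0.227 | predicted damaging fraction among missense variants in the assayed domain |
| `mu_functional`, `mu_nonfunctional` | 0.0, −1.2 | separation ≈ 8 component SDs so control calibration is unambiguous |
| `sigma_functional`, `sigma_nonfunctional` | 0.15 | within-component spread of latent effects |
| `batch_location_sd`, `batch_logscale_sd` | 0.05 | mild batch structure, comparable to residual noise |
| `t_df`, `residual_scale` | 6, 0.1 | heavy-tailed but finite-variance replicate noise |
| `assay_offset`, `assay_scale` | 0.5, 1.3 | detectable but benign affine distortion |
| `missing_rate` | 0.02 | sporadic dropout |

Synonymous variants are always functional and nonsense variants always
non-functional; canonical-splice variants are treated as loss-of-function.
Annotations (BayesDel-like score, splice flag, population frequency,
sparse ClinVar/HDR standards) are drawn consistently with the latent
status so the classification layer can be tested end to end.

What the generator does **not** emulate: read counts and count noise,
gRNA-level structure, time-course kinetics, position-specific effects
within an exon, informative missingness, and ambiguous/intermediate
functional effects (hypomorphs). Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed mixture
structure, not performance on real screens, where component overlap and
unmodelled structure will lower accuracy.

## Harmonization

The second assay is mapped onto the first by the unique affine transform
sending its synonymous-control and nonsense-control medians onto the
reference assay's. Medians are used because the noise model is
heavy-tailed; anchors are pooled over replicates within an assay because
absorbing replicate-level differences is precisely the role of the model's
batch random effects. A non-positive fitted slope (the assays running in
opposite directions) is an error rather than silently flipping ranks.
Variants seen in only one assay are flagged, not dropped; the CLI filters
them by default (`--common-only`).

## The hierarchical model and its sampler

`VarCallModel` embeds a two-component Gaussian mixture over latent variant
effects in a measurement model with replicate-by-exon location and scale
random effects and t errors. Pathogenicity indicators are pinned for
controls (synonymous → functional, nonsense → non-functional) and sampled
with prior π (default 0.2, alternative 0.1 for sensitivity analysis) for
all other variants.

The sampler is Metropolis-within-Gibbs, written in NumPy:

- t errors are represented by their Gamma scale mixture, making θ, z, the
  component means/variances and the location batch effects conjugate;
- the component means are updated as ordered truncated normals
  (μ_N < μ_F), which prevents label switching;
- the residual scale τ and degrees of freedom ν are updated by random-walk
  Metropolis on the *marginal* t likelihood (the scale mixture collapsed),
  which removes their coupling to the latent precision multipliers; the
  multipliers are redrawn from their full conditional immediately after,
  so the partially collapsed ordering remains valid;
- log-scale batch effects g get vectorized random-walk Metropolis sweeps
  with per-batch step-size adaptation during warmup;
- both random-effect scales (σ_b, σ_g) additionally get an interweaving
  (ASIS) move — with the standardized effects held fixed, the scale and
  the effects are rescaled jointly — without which these weakly identified
  scales dominate the autocorrelation time.

Priors are weakly informative and scale-aware: Normal on component means
centred at the control medians with variance 25× the data variance;
Inverse-Gamma(2, ·) on the component, residual and batch variances (the
conditionally conjugate family; the batch-variance prior scale is small,
1e-4, so batch effects shrink to zero when the data carry no batch
structure); Gamma(2, 0.1) truncated to ν > 2. Defaults: 2 chains, 500
warmup iterations, 1000 retained draws at thinning 4, seed 20260409.
Convergence requires R-hat ≤ 1.05 and pooled ESS ≥ 400 on every free
hyperparameter; otherwise the fit is returned flagged `converged_ = False`
(the CLI exits non-zero).

Posterior probabilities are clamped to [1/(S+1), S/(S+1)] (S = retained
draws) before the odds conversion so pinned controls receive finite,
maximal-strength Bayes factors. Evidence categories come from comparing
the BF against powers of the odds constant 350 (strong C^1/2, moderate
C^1/4, supporting C^1/8, reciprocals for benign); the constant and
exponents are configuration values with these defaults.

## The Gaussian-mixture model

`FunctionalGMM` summarizes each variant by the mean (configurable to
median) of its harmonized replicate scores and fits a two-component
Gaussian mixture by EM: 10 restarts (one deterministic quantile-based
start plus random pairs), convergence at Δ log-likelihood < 1e-8 or 500
iterations, variance floor 1e-6, best restart kept, and the log-likelihood
trace asserted non-decreasing. Components are labeled by control
responsibility — the component carrying the nonsense controls is
non-functional — rather than by fitted order. The likelihood ratio of the
two component densities is the odds of pathogenicity, compared against the
same seven-category thresholds as the hierarchical model so both models
share one strength scale; the mixture weight is fitted freely and the
prior π enters only the PIF posterior, keeping the evidence separable from
the prior. No further rescaling of PIF beyond component labeling is
applied.

## Concordance, evaluation, classification

Concordance between two call sets is judged at the side level (any
pathogenic strength = P, any benign strength = B, Uncertain = VUS) — the
rule under which discordant variants are denied functional weight — with
exact seven-level agreement and the 7×7 confusion matrix reported
separately.

Evaluation against standards supports a conservative definition
(sensitivity from `P_Strong` calls only; specificity from
`B_Strong`/`B_Moderate`) and an all-categories definition (any P side vs
any B side). Standards whose call is Uncertain stay in the denominator but
are not counted as conflicts; only opposite-side calls are "discrepant",
and only those trigger the VUS-discordant override in the classifier. The
burden test is the pooled 2×2 Fisher exact test with a Haldane +0.5
correction for zero cells and a Wald CI on the log odds ratio;
covariate-adjusted regressions on clinical cohorts are out of scope.

The points engine derives three code families internally — functional
PS3/BS3 with strength set by the seven-level category and structurally
capped at ±4; frequency BA1/BS1/BS1_Supporting from the filter allele
frequency (thresholds 0.001 / 0.0001 / 0.00002) with PM2_Supporting for
variants absent from the population, treated as mutually exclusive with
the frequency codes; in-silico PP3 (moderate at BayesDel ≥ 0.3,
supporting for splice-prediction hits) and BP4 below a benign BayesDel
cutoff of 0.15, a configuration value sourced from expert-panel practice
rather than derived here. All other codes (PVS1, PS1, PM3, PM5, PP4, BP5,
BS2, BP7) need external clinical or literature data and are consumed as
pre-assigned `CODE:strength` inputs; the engine validates
mutual-exclusion rules and sums points. Every variant is classified twice,
with and without the functional code, and VUS_discordant counts as VUS in
classified-fraction summaries.

## Problem sizes and numerical choices

The default test and acceptance workloads use a 500-variant screen for
model fits, a 50-variant batch-free instance for the closed-form
posterior cross-check, a 30-variant instance for the EM-vs-grid-search
oracle, and 1000 simulated tables for burden-test calibration — sizes at
which every check is stable across seeds while the whole suite stays
fast. Degenerate inputs are handled explicitly: constant summary scores
are an error for the mixture; vanishing EM variances hit the variance
floor and, if all restarts degenerate, an error; equal control medians are
an error for the harmonizer; empty mixture components in the sampler fall
back to their priors.

## Limitations

- The generator's clean two-component separation makes the end-to-end
  accuracy targets nearly saturated; real screens with overlapping
  components will show intermediate posterior probabilities and more
  Uncertain calls.
- The scale random effects g are weakly identified when most latent
  effects sit near zero; their posterior shrinks toward the prior in that
  regime (visible as underestimation of σ_g when σ_b, σ_g are both
  nonzero but small).
- The exact prior families of the original hierarchical formulation are
  not public; the weakly informative choices above are this package's
  own, and the prior-sensitivity run (π = 0.2 vs 0.1) is the supported way
  to probe their influence on categories.
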