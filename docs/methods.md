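# Methods

This note records the models implemented in `xtrait`, the assumptions they
make, the numerical choices that were genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## The synthetic study generator

All validation rests on `xtrait.simulate`, which generates marginal GWAS
summary statistics directly at the z-score level.  Within each of B
LD-independent regions with correlation matrix R, trait t's z-scores are

    z_t = √n_t · R γ_t + ε_t,   ε_t ~ N(0, R),
    cov(ε_1, ε_2) = (ρ_pheno · n_s / √(n1 n2)) · R,

where γ are sparse per-SNP causal effects drawn bivariate normal over a
random causal set (per-trait variance h²/M_c, correlation r_g).  This is
exactly the sampling model the downstream moment estimators assume, so the
experiments are parameter-recovery tests, not tests against real-data
artefacts.

Defaults (the package's reference study conditions):

* **Scale**: 100 regions × 200 SNPs (M = 20,000) — the genome's ~1,700-region
  LD partition at roughly 1/17 scale; regions sit > 1 Mb apart so clumping
  windows never span regions.
* **LD**: AR(1) within regions, decay varying linearly from 0.2 to 0.95
  across regions.  The gradient matters: real LD strength varies regionally,
  and a panel whose LD scores are nearly constant leaves the LD-score
  regression slope unidentified.  With the gradient, per-SNP LD scores span
  ~1–19.
* **Architecture**: prop_causal = 0.2 (4,000 causal SNPs at default scale).
  Dense polygenicity matches the brain/metabolic traits being emulated and
  keeps each region's realized heritability close to its expectation, so
  region-level jackknife SEs reflect the real sampling noise.
* **Samples**: N = 50,000 per trait, no overlap unless requested; overlap
  enters only through the correlated-noise term above, i.e. only the
  cross-trait intercept, not the slope.
* **Allele frequencies** uniform in (0.05, 0.5); z ↔ (β, SE) conversion via
  SE = 1/√(2p(1−p)(n+z²)), β = z·SE.

What the generator does **not** emulate: genotyped individuals (an optional
Gaussian "dosage" reference panel exists for estimated-LD experiments, and
is labelled synthetic), binary-trait liability scale (effects are
observed-scale throughout), population stratification, imputation artefacts
in the input GWAS, and cross-region LD.  Passing tests therefore show the
estimators are correct under their own sampling model at toy scale; they do
not certify behaviour under real-data confounding.

## Imputation

Conditional-normal ("summary-statistics") imputation per region:
z_t = R_to (R_oo + λI)⁻¹ z_obs with quality r² = diag(R_to(R_oo+λI)⁻¹R_ot).
λ defaults to 0.1/√n_ref (sampling noise in an estimated reference panel
shrinks with panel size); imputed SNPs with r² < 0.6 are discarded,
boundary inclusive (the filter removes strictly-below-threshold records).
Imputation is strictly within-region; cross-region LD is zero by panel
construction.

## LD-score regression

Two-step weighted least squares: first pass with null-model weights, second
pass with heteroskedasticity weights 1/(2(intercept + h²Nℓ/M)²ℓ) (and the
cross-trait analogue).  Standard errors by delete-a-block jackknife over
position-contiguous blocks; the block count is capped at ⌊SNPs/50⌋, and in
the recovery experiments 100 blocks are used so each jackknife block is at
least one LD region — blocks smaller than a region leave out data
correlated with what remains and understate the SE.  Inside `estimate_rg`
the two heritabilities entering r_g = ρ_g/√(h²₁h²₂) are re-fit with the
same weights as the cross-trait regression; this shares one weighting
scheme across numerator and denominator and makes r_g exactly 1 when both
inputs are the same trait.  The intercept is constrained to zero
automatically when |gcov_int| < 1.96·SE ("not significantly different from
zero"); the flag records which branch ran.  matSpD's effective trait count
defaults to the eigenvalue-variance (Nyholt) form with the Li–Ji count
available.

## Regional pleiotropy (pairwise Bayesian analysis)

All Bayes-factor arithmetic is in log space (ABFs overflow doubles near
|z| ≈ 40).  The prior-variance grid is {0.01, 0.1, 0.5} with equal weights.
Priors over the five regional models are estimated by EM on the regional
Bayes factors (monotone in the mixture log-likelihood, uniform start,
best-iterate fallback); a fixed prior vector is accepted where an analysis
wants the estimation switched off.  Model 4's Bayes factor excludes the
diagonal (same-SNP) products, computed with a guarded
log(exp(a) − exp(b)); a single-SNP region makes model 4 impossible (BF 0).
Classification is strict: PPA3 > 0.9 significant, > 0.5 suggestive.

## Meta-analysis

Fixed effects is inverse-variance weighting.  RE2 is the likelihood-ratio
test of (μ=0, τ²=0) against (μ free, τ² ≥ 0).  The usual asymptotic null
for this boundary problem, ½χ²(1)+½χ²(2), is measurably miscalibrated with
only two studies — simulated type-I error 0.027 at nominal 0.05 — so for
k = 2 the package derives the exact null: with standardized effects
u = (x₁+x₂)/√2, v = (x₁−x₂)/√2, the LRT statistic is
u² + (v²−2−2·log(v²/2))·1[v² > 2], giving

    P(stat ≥ t) = E_v[ χ²₁ tail at max(t − g(v), 0) ],

evaluated by one-dimensional Gaussian quadrature (341-node grid to |v|=8.5).
This is exact for equal SEs, a close approximation otherwise, and restores
type-I error to 0.049–0.052 in simulation; the asymptotic mixture is kept
for k > 2.  m-values are computed by exact enumeration over presence
configurations (prior N(0, 0.2²) effect, Bernoulli(0.5) presence — the
conventional defaults; enumeration refuses k > 20).  Because the switch
rule between FE and RE2 is an analyst choice, the per-SNP table reports
both and a `chosen` column using Cochran's Q p < 0.05 as the heterogeneity
trigger.  Binary and continuous traits are meta-analysed on their native
scales.

## Clumping

Greedy best-p-first in two passes (r² ≥ 0.6 then ≥ 0.1 within ±1 Mb,
lead-to-candidate distance, not transitive chains), ties on p broken by
position then id so output is independent of input order.  Novelty is the
LD rule only: a lead in r² > 0.1 with any supplied known hit is `known`,
otherwise `putative_novel`; leads absent from the panel are `unassessed`.
External catalogue lookups are out of scope.  Nearest-gene annotation
reports all equidistant genes.

## Mendelian randomization

Instruments: exposure p < 5×10⁻⁸, greedy LD pruning (r² < 0.05 within
1 Mb); if fewer than 10 survive, selection reruns at p ≤ 1×10⁻⁵ and the
threshold used is recorded.  Ratio estimates use first-order SEs
(se_y/|b_x|); the estimators assume instrument-effect noise is small
relative to b_x, and the weighted median's robustness guarantee is likewise
asymptotic in instrument precision.  MR-Egger orients b_x ≥ 0, weights by
1/se_y², and uses a multiplicative overdispersion factor bounded below by 1
with t(k−2) reference.  MR-PRESSO simulates outcome effects around
leave-one-out expectations, recomputing the leave-one-out estimates inside
every draw so the global RSS test is calibrated (simulated coverage ~95%);
outliers are Bonferroni-flagged per-instrument simulation p-values, and the
distortion p compares the outlier-free estimate against removals of random
same-size subsets; p-values use the add-one rule (minimum 1/(1+n_sim)).
The reference MR-PRESSO also perturbs the exposure effects; treating b_x as
fixed is a documented simplification that leaves the null calibration
intact in simulation.  GSMR is single-pass: a weighted-median initial
estimate (bootstrap SE), HEIDI removal of instruments with two-sided
deviation p < 0.01 — which by construction discards ≈1% of valid
instruments — then GLS under the instrument LD correlation; with identity
LD the GLS collapses to fixed-effect IVW exactly.  The study-wide threshold
is α/(M_eff·2) for forward plus reverse experiments.

## Latent causal variable

The LCV model: normalized genetic effects x = q₁L + u₁, y = q₂L + u₂ with
a shared latent trait L; ρ = q₁q₂, and the genetic causality proportion is
defined through q₁² = |ρ|^(1−gcp), q₂² = |ρ|^(1+gcp) (gcp = 1: trait 1 *is*
the latent trait).  The estimator uses excess mixed fourth moments
κ₃₁ = E[x³y] − 3ρ and κ₁₃ = E[xy³] − 3ρ of the variance-normalized
z-scores: Gaussian sampling noise and independent trait-specific effects
cancel exactly from both, leaving κ₃₁/κ₁₃ = q₁²/q₂² times a ratio of
genetic-scale factors.  After attenuation-correcting ρ to the genetic scale
(signal fraction t = (E[z²]−1)/E[z²], the LDSC decomposition of mean
chi-square), the moment-ratio equation

    gcp = −log((|κ₃₁|/|κ₁₃|)·t₂/t₁) / (2·log|ρ_g|)

is solved directly and clipped to [−1, 1]; the jackknife (100 contiguous
blocks) runs on the unclipped equation.  LD scores, when supplied, enter as
downweights 1/max(1, ℓ).  The estimator needs a leptokurtic effect-size
distribution — with exactly Gaussian effects the moments carry no signal —
which sparse (spike-and-slab) architectures provide; this is the same
identifiability requirement the published estimator has.  Exact
antisymmetry under trait swap holds by construction.  Warnings are recorded
for |ρ_g| < 0.05 (weak identification) and, when heritability z-scores are
supplied, z < 7 (low power).  The published estimator's exact
quasi-likelihood constants are not reproduced; the validation surface is
parameter recovery (causal vs shared architectures), not numeric identity
with the reference implementation.

## Gene-level pipeline

SNPs map to every gene whose ±10 kb-padded interval contains them.  GATES
needs the correlation of *p-values*, not of genotypes: under bivariate
normality corr(p_i, p_j) is an even function of r, fitted here by
Gauss–Hermite quadrature as (0.5906r² + 0.3646r⁴ − 0.3565r⁶ + 0.3955r⁸)
normalized to 1 at |r| = 1 (max fit error ~0.006).  Using |r| directly
overstates dependence and pushed simulated GATES type-I error to 1.45×
nominal; with the transform it is ≤ 1.2× at α ∈ {0.05, 0.01} over 10⁴
LD-correlated null genes.  Effective SNP counts are
m_e = k − Σ_{λ>1}(λ−1).  Effective gene counts partition best SNPs in
genome order into blocks broken where consecutive r² < 0.1 and sum per-block
m_e; the overlap test runs that count on each relevant gene set directly
(discovery hits, overlap, target hits, common-gene universe), rounds
half-up to integers, and applies the one-sided exact binomial against the
target-derived expected proportion.  Fisher's combined p is the χ²(4) tail;
the shared-gene screen requires p_FCP < 0.05/M_eff (strict) plus nominal
support in both traits.

## Pipeline

`run_pipeline` expands one global seed into per-stage seeds by
seed·1000003 + stage-index (mod 2³¹−1), so partial reruns reproduce
deterministic outputs bit for bit; the manifest records status, parameters
and wall time per stage, failed stages halt their dependents only.

## Problem sizes in the validation suite

The recovery experiments use the reference scale above (M = 20,000;
100 seeds for genetic-correlation recovery, 200 regions per scenario for
regional-model discrimination, 10⁴ null pairs for RE2 calibration, 500
replicates for the MR estimator recoveries, 10⁴ instruments for the HEIDI
null rate, 50 seeds per LCV architecture, 10⁴ genes for GATES calibration,
500 replicates for overlap-test uniformity).  These sizes were chosen so
each check pins its statistic well inside its tolerance while the whole
suite stays conveniently fast on one core.

## Known limitations

Observed-scale effects only (no liability transformation); no partitioned
or annotation-stratified LD-score regression; no multivariable MR, Steiger
filtering, or iterative GSMR re-estimation; RE2 limited to two studies by
design; the p-value-correlation polynomial assumes bivariate-normal test
statistics; pathway enrichment and external GWAS-catalogue novelty checks
are out of scope.
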