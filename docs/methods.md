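# Methods

## Model and assumptions

For one locus with M SNPs observed in Q studies, the observed per-study
Z-scores are modeled as `S_q | Λ_q ~ N(Λ_q, Σ_q)` with `Λ_q = Σ_q Λ_Cq`: LD
propagates the causal non-centrality parameters (NCPs) to tag SNPs. Causal
statuses are a binary configuration vector `C` with independent
Bernoulli(γ) prior entries. The random-effects layer ties studies together:
a causal SNP has a global mean NCP `λ_m ~ N(0, σ²)` and each study draws its
own NCP around it with variance τ², scaled by `√(N_q/N_min)` when sample
sizes differ. Integrating the latent NCPs out analytically (normal conjugacy)
gives

    S | C ~ N(0, Σ + Σ Σ_C Σ),
    Σ_C = (τ² I_Q + σ² 1_Q 1_Qᵀ) ⊗ diag(C)        (study-major layout),

generalized to `σ²_{q1q2} = √(N_q1 N_q2) σ_g²` for unequal sample sizes,
with `σ_g² = σ²/N_min`. Key assumptions: studies are independent given C;
causal SNPs are shared across studies (a variant causal in only one
population violates the model and can inflate set sizes); heterogeneity τ²
is common to all studies; causal effect sizes are mutually independent.

The posterior of a configuration is `P(C|S) ∝ P(S|C) P(C)`, normalized over
all configurations with 1..K causal SNPs. The ρ*-confidence set is the
smallest SNP set whose *compatible* configurations (those with no causal SNP
outside the set) carry posterior mass ≥ ρ*.

## Parameters

| parameter | default | meaning |
|---|---|---|
| σ (`ncp_scale`) | 5.2 | SD of a causal SNP's mean NCP, assigned to the smallest study; 5.2 is the Z-score whose two-sided p-value is 5e-8, so borderline genome-wide-significant SNPs are well covered by the prior. Dimensionless (Z-score scale). |
| τ² (`tau_sq`) | 0.52 | Between-study heterogeneity variance of per-study NCPs, 10% of σ; chosen to give power against both small and large heterogeneity. Small misspecifications are benign. |
| γ (`gamma`) | 0.01 | Prior causal probability per SNP, the convention of the single-study lineage this model extends. |
| K (`max_causal`) | 3 | Maximum simultaneously causal SNPs searched; the search space is Σ_k C(M,k), so runtime grows steeply in K. |
| ρ* (`rho_star`) | 0.95 | Confidence level of the causal set. |
| ϵ (`epsilon`) | 0 | Legacy ridge on the non-causal diagonal of Σ_C, only meaningful on the dense path; the low-rank path removes the full-rank requirement, so the default is 0. |
| truncation | 1e-8 (relative) | Eigenvalues of an LD matrix below this fraction of the largest are dropped in the low-rank path. |

τ² is fixed, not fitted: fitting it per locus risks overfitting the very
heterogeneity the model is meant to absorb.

## Likelihood computation

Three routes, identical posteriors on full-rank LD (tested, not assumed):

* **Dense** — literal (MQ × MQ) MVN evaluation; the oracle.
* **Fast** — factor Σ out: `Sᵀ(Σ+ΣΣ_CΣ)⁻¹S = SᵀΣ⁻¹S − S_Jᵀ Σ_cc (I + Σ_JJ
  Σ_cc)⁻¹ S_J` and `|Σ+ΣΣ_CΣ| = |Σ|·|I + Σ_JJ Σ_cc|` via the
  Woodbury/Sylvester identities, where J are the KQ causal row indices,
  Σ_cc the nonzero block of Σ_C, and Σ_JJ the causal submatrix of Σ.
  `SᵀΣ⁻¹S` and `log|Σ|` are computed once per locus and cached; each
  configuration then costs a (KQ × KQ) solve — O(K³Q³) instead of O(M³Q³).
* **Low-rank** (default) — per-study eigendecomposition `Σ_q = W Ω Wᵀ` with
  near-null directions truncated; the statistics are rotated to
  `S' = Ω^(-1/2)WᵀS`. Because `Cov(S') = I + A Σ_C Aᵀ` with
  `A = Ω^(1/2)Wᵀ` exactly, the same (KQ × KQ) reduction applies with
  `G = (WΩWᵀ)_JJ` and `t = (WWᵀS)_J`. This path is finite for singular LD
  and, on full-rank LD, differs from the dense value only by the constant
  Jacobian ½Σlog ω, so normalized posteriors coincide.

A scale-convention variant of the low-rank covariance, `I + m·BΣ_C Bᵀ` with
`B = Ω^(-1/2)Wᵀ` and m the number of SNPs, appears in parts of the low-rank
fine-mapping literature; it is available behind `printed_form=True` for
cross-checking but is not posterior-equivalent to the dense model, so the
exact transform is the default.

Numerical choices: all posterior arithmetic is in log space with log-sum-exp
normalization (probability-space products underflow beyond M ≈ 100);
eigenvector signs follow a fixed convention (largest-magnitude component
positive) so rotated statistics are reproducible; configurations of equal
cardinality share their Σ_cc and are evaluated in stacked batches; the
scalar fast path falls back to the dense evaluation with a warning if its
Woodbury core is ill-conditioned. The all-zero configuration is excluded
from the normalizing sum by default — the tool is intended for loci with a
significant signal, and the set semantics presume ≥ 1 causal SNP — with an
`include_null_config` switch for sensitivity analysis.

## Confidence-set construction

The objective (smallest set with compatible mass ≥ ρ*) is searched greedily:
SNPs are added in descending PIP order (ties broken by input order, so
output is deterministic) and the exact compatible-configuration mass is
recomputed after each addition; the reported set probability is that exact
mass, not the PIP sum. Exhaustive subset search is exponential in M and is
used only as a test oracle at M ≤ 10, where the greedy set size matches the
exhaustive minimum in ≥ 95% of random instances (measured, not assumed) and
by construction never undershoots it.

## Synthetic data

`simulate_summary_direct` draws from the generative model itself: causal
SNPs uniform (resampled until all pairs are non-negatively correlated in
every study), mean NCP `|N(5.2, 1)|` — magnitudes only, so causal signals
point consistently across studies — per-study NCPs `N(λ_m √(N_q/N_min), τ²)`,
and `S_q ~ N(Σ_q Λ_Cq, Σ_q)`. The default design is the desk-scale scenario
used throughout the tests: Q = 2, M = 50, AR(1) LD with r = 0.9 vs r = 0.5,
1–2 causal SNPs, 100 replicates, seeded.

One published variant of this simulation draws effect sizes on the β scale
with a corrupted-looking distribution; the ambiguity (variance 1 on the β or
the NCP scale) is resolved here by simulating in NCP space, which is the
scale σ and τ² live on, with the genotype route below for users who want the
β-scale interpretation.

`simulate_genotype_path` provides the genotype → phenotype → regression
route: Gaussian-copula genotypes thresholded at the target minor allele
frequency (MAF ≥ 1% enforced), phenotype `y = Xβ + e` with environmental
variance `var_g (1/h² − 1)` scaling to the target heritability
(interpreted per causal SNP), per-SNP marginal-regression Z-scores, and
in-sample LD. Because thresholding attenuates latent correlations, the
latent matrix is inverse-adjusted by tetrachoric-style root finding on the
bivariate normal CDF and projected back to a valid correlation matrix; the
realized genotype correlations then track the target LD to within ~0.05 at
N = 5000.

What the generator does *not* emulate: real haplotype structure and
recombination-hotspot LD (AR(1)/block LD is a stylization), population-
specific allele-frequency differences, untyped causal variants, study-
specific imputation error, and causal variants private to one population.
Passing calibration here therefore shows the inference is correct *under the
model*, not that the model matches any particular cohort.

## Evaluation harness

`evaluate_calibration` reports sensitivity (fraction of replicates whose
returned set contains all true causal SNPs), mean/median set size, and the
mean number of SNPs taken in descending PIP order until every causal SNP is
covered, plus the full per-replicate table. Under the model-faithful
generator the ρ* = 0.95 set is expected to cover all causal SNPs in ≥ 95% of
replicates; `scripts/acceptance.py` recomputes exactly this quantity. Problem
sizes throughout (M = 50, Q = 2, 100 replicates; oracle comparisons at
M ≤ 30) are the package's desk-scale defaults — large enough for stable
proportions, small enough to iterate on.

## Known limitations

* Enumeration over Σ_k C(M,k) configurations: loci of many hundreds of SNPs
  with K > 3 become expensive; no stochastic search is implemented.
* One τ² for all studies: grouping studies by population and meta-analyzing
  within groups first is the recommended workaround when several studies
  share a population.
* The set is returned whole; it is not partitioned into per-signal credible
  subsets.
* Uniform γ only; no functional/annotation-informed priors.
* Allele harmonization is the caller's responsibility (a heuristic warning
  flags suspicious sign patterns among high-LD pairs).
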