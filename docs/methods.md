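# Methods

## Model

Genotype at a biallelic exonic SNP is a latent variable g ∈ {0, 1, 2}
counting copies of the alternative allele. Conditional on total depth n,
the alt-supporting read count k is beta-binomial,
k | g ~ BB(n, μ_g, κ_g), and marginally a three-component mixture with
weights θ. The beta-binomial arises by integrating a per-site allelic
fraction p ~ Beta(α_g, β_g) out of a binomial — exactly the mechanism by
which allele-specific expression makes the heterozygote fraction itself
random across sites. Assumptions worth keeping in mind:

* sites are independent given the parameters (no linkage, no shared gene
  effects between nearby SNPs);
* one set of (θ, μ, κ) describes all sites of a sample — component
  parameters are a property of the sequencing/alignment process and the
  study's expression biology, which is what makes them transferable across
  samples of the same study;
* the site list is given and biallelic; discovery and indels are out of
  scope.

### Parameterization

We work in (μ, κ): μ_g = α_g/(α_g+β_g) is the mean alt fraction and
κ_g = α_g+β_g the concentration. Small κ means strong overdispersion; as
κ → ∞ the component collapses to Binomial(n, μ). The (0,1)-scale
overdispersion λ_g = 1/(1+κ_g) is reported as a derived quantity
(`ComponentParams.lambda_overdisp`), but the sampled scale parameter is κ:
the Gamma(α_g+β_g, 1) prior used for the scale has essentially all its mass
above 1 and is only coherent on the concentration scale, and with κ_g the
Beta/Gamma prior pair matches the stated hyperparameters exactly.

### Priors (defaults)

| parameter | prior | implied centre |
|---|---|---|
| θ | Dirichlet(1, 1, 1) | flat on the simplex |
| μ_0 | Beta(1, 499) | 0.002 (hom-ref error rate) |
| μ_1 | Beta(10, 10) | 0.5, sd ≈ 0.11 (het, weakly informative) |
| μ_2 | Beta(499, 1) | 0.998 |
| κ_g | Gamma(α_g+β_g, 1) | 500 / 20 / 500 |

The homozygote priors are sharp because those components describe
sequencing/mapping error, which is small and stable; the heterozygote prior
is deliberately loose so the data can express mapping bias (μ_1 < 0.5) and
ASE overdispersion (small κ_1). Component identity is fixed by constraining
μ_0 < μ_1 < μ_2, which also resolves label switching.

## Inference

Training sites are a uniform random subsample (default 1000) of sites with
depth ≥ 10; the depth filter applies to training only — calling handles all
depths. The posterior ∝ likelihood × prior, with genotype labels
marginalized analytically inside the likelihood, is sampled by an adaptive
Metropolis-within-Gibbs on unconstrained coordinates:

* θ via a stick-breaking transform (2 logits, with its log-Jacobian);
* logit μ_g and log κ_g, updated as separate scalar random walks per
  component (a joint (μ_g, κ_g) block was tried first and mixed poorly for
  the near-boundary hom-alt component; scalar updates give ESS in the
  hundreds-to-thousands for every parameter at the default budget);
* the ascending-μ constraint enforced by proposal rejection (prior
  truncation), which is exact Metropolis on the truncated target.

Proposal scales adapt by Robbins–Monro toward 0.38 acceptance during warmup
only and are frozen afterwards, so kept draws form a valid chain. Defaults:
4 chains, 1000 warmup + 1000 kept per chain (4000 draws). Likelihood
evaluations aggregate duplicate (k, n) pairs and cache per-component
columns, so one update costs one column recomputation; a default fit takes
a few seconds. Chains are seeded from independent spawned streams of the
user seed; runs are bitwise reproducible.

Convergence is summarized per scalar parameter by split-chain R̂ and
effective sample size (computed via arviz; the split-R̂ formula is
cross-checked in the tests against a direct implementation). The fit is
flagged converged when all R̂ < 1.05; the CLI treats non-convergence as a
warning unless `--strict`.

A fitted model (draws + priors + summary + config) serializes to a JSON
file, enabling fit-once/call-many across samples.

## Calling

Per site, P(g | k, n) ∝ π_g · S⁻¹ Σ_s BB(k | n, μ_g⁽ˢ⁾, κ_g⁽ˢ⁾): the
component likelihood is averaged over posterior draws, propagating
parameter uncertainty into the call (important at low depth, where a
plug-in posterior mean is overconfident). A plug-in mode
(`point_estimate=True`) and draw thinning (`max_draws`) exist for speed.
π is the posterior-mean θ by default; Hardy–Weinberg probabilities from a
supplied allele frequency are an option. Sites with no reads return π
unchanged and are never hard-called at any threshold above max(π).

Hard calls report argmax_g P(g) when P ≥ threshold (default 0.99,
inclusive boundary; argmax ties break to the smaller genotype). Dosage
P(1) + 2·P(2) is always populated. Output is a single-sample VCF 4.2 with
GT:GP:DS:DP (GP rounded to 4 decimals and renormalized; missing calls as
`./.`) plus a flat TSV mirror.

## Baseline and benchmarking

The count-threshold baseline calls from r = k/n alone: r < t → 0,
r > 1−t → 2, else 1, with t ∈ (0, 0.5) (default 0.1) and band boundaries
inclusive to het (t = 0.5 would make the band degenerate, hence the open
bound). Concordance against a gold standard is stratified by the truth
genotype; missing calls are tallied but excluded from accuracy
denominators; truth entries outside {0,1,2} are excluded, not counted as
errors; comparisons default to sites with depth ≥ 10. het→hom and hom→het
errors are counted separately because their downstream costs differ
(hom→het fabricates ASE signal). Dosage concordance rounds dosages
half-away-from-zero to compare against integer truth — the natural hard
comparison rule for continuous dosages.

## Simulator

`simulate_counts` draws g ~ Categorical(θ) (or Hardy–Weinberg from an
allele frequency), depth from fixed / Poisson / negative-binomial models,
and k from the beta-binomial via its beta-mixing representation. Defaults —
θ = (0.6, 0.25, 0.15), μ = (0.002, 0.48, 0.998), κ = (500, 20, 500),
Poisson depth with mean 30 — describe a realistic expressed-SNP panel:
roughly 60% of calls homozygous-reference, a het mean pulled below 0.5 by
reference mapping bias, strong het overdispersion from ASE, and
near-deterministic homozygotes. The negative-binomial depth model mimics
the high between-gene coverage variability of RNA-seq. `simulate_cohort`
derives per-sample seeds deterministically and can perturb parameters
between samples (logit-μ sd 0.05, log-κ sd 0.1) to mimic between-individual
variability.

What the simulator does **not** emulate: alignment artifacts and
position-dependent mapping bias, splice-junction read loss, correlated
errors within a gene, sample swaps, or truth-set errors. Passing tests
therefore demonstrate correctness of the method under its own model and
realistic parameter regimes — not performance on real alignments, which
depends on the upstream counting pipeline.

## Numerical choices

* All probability computation in log space (log-gamma / log-beta
  functions); mixtures via log-sum-exp. Depths up to 10⁶ are safe.
* A site with n = 0 contributes log-likelihood 0 (pmf 1): no data, neutral
  evidence.
* Simplex sums validated to 1e-8 and renormalized exactly on construction.
* Boundary parameter values get prior density −∞ rather than exceptions
  during sampling; constructors of user-facing types reject them loudly.
* EAF filter is a strict inequality (> 0.01): a site at exactly the cutoff
  is removed. BED exclusion converts 0-based half-open intervals to 1-based
  positions, so interval (100, 101] in 1-based terms covers position 101
  only.
* Test and acceptance problem sizes (4000-site samples, 1000 training SNPs,
  15 recovery replicates) were chosen as the smallest sizes at which the
  statistical checks have comfortable Monte-Carlo margins.

## Known limitations

* The sampler is random-walk based; posteriors with much larger training
  sets (≥ 10⁵ sites) would benefit from gradient-based sampling.
* Mixture weights θ are shared across all sites; per-site allele-frequency
  priors are available only through the Hardy–Weinberg calling mode.
* No per-base quality weighting: counts are taken at face value, so
  upstream filtering (mapping quality, duplicates) determines input
  quality.
* Multi-allelic sites are rejected at parse time rather than modelled.
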