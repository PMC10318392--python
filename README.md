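# betacall

Probabilistic genotyping from RNA-seq allele counts with a learned
beta-binomial mixture.

## The problem

Calling genotypes from RNA-seq reads is attractive — it covers exactly the
exonic SNPs that allele-specific-expression (ASE) and eQTL analyses need —
but standard DNA genotypers ignore two RNA-specific sources of variation:

* **Allele-specific expression.** At a heterozygous site, cis-regulatory
  variation can over-amplify one chromosome's allele, pushing the alt-read
  fraction far from 1/2 and inflating its variance well beyond binomial.
* **Reference mapping bias.** Reads carrying the reference allele align
  slightly more often, shifting the heterozygote mean below 0.5.

Both errors matter most in ASE itself: a homozygote miscalled as
heterozygous fabricates a perfect allelic-imbalance signal.

## The model

At SNP *l* with total depth *n<sub>l</sub>*, the alt-supporting read count
*k<sub>l</sub>* follows a three-component beta-binomial mixture over the
latent genotype *g* ∈ {0, 1, 2} (copies of the alternative allele):

$$
p(k_l \mid n_l) \;=\; \sum_{g=0}^{2} \theta_g \,
\mathrm{BB}\!\left(k_l \mid n_l,\ \mu_g,\ \kappa_g\right),
$$

where each component has mean μ<sub>g</sub> ∈ (0,1) and concentration
κ<sub>g</sub> = α<sub>g</sub> + β<sub>g</sub> (overdispersion
λ<sub>g</sub> = 1/(1+κ<sub>g</sub>) is reported as a derived quantity).
Priors: θ ∼ Dirichlet(1,1,1), μ<sub>g</sub> ∼ Beta(α<sub>g</sub>, β<sub>g</sub>)
with (α, β) hyperparameters (1, 499), (10, 10), (499, 1), and
κ<sub>g</sub> ∼ Gamma(α<sub>g</sub>+β<sub>g</sub>, 1).

The workflow is *learn once, call many*: the posterior of (θ, μ, κ) is
sampled by MCMC from a random training subset of well-covered SNPs (default
1000 sites with ≥ 10 reads), and genotypes are then called per individual at
every site by averaging the component likelihood over the posterior draws:

$$
P(g \mid k, n) \propto \hat\theta_g \cdot
\frac{1}{S}\sum_{s=1}^{S} \mathrm{BB}\!\left(k \mid n, \mu_g^{(s)}, \kappa_g^{(s)}\right).
$$

Each site gets a genotype posterior (VCF `GP`), a dosage
Σ<sub>g</sub> g·P(g) (`DS`), and a hard call (`GT`) reported only when the
top posterior probability reaches a threshold (default 0.99). Because the
learned read-count distributions are a property of the study, not of one
individual, a model fitted on one sample (or a pooled sample) transfers to
the rest of the cohort.

Also included: a naive count-threshold baseline (alt fraction < t → hom-ref,
> 1−t → hom-alt, else het; default t = 0.1), concordance benchmarking
stratified by truth genotype with het→hom / hom→het error counts, and a
simulator of the generative model.

## Worked example

```python
from betacall import (SimConfig, simulate_counts, select_training_snps,
                      fit_mixture, diagnose, call_sample, concordance_by_genotype)

sim = simulate_counts(SimConfig(n_sites=4000, seed=7))
training = select_training_snps(sim.counts, requested_size=1000, min_depth=10, seed=7)
draws = fit_mixture(training, seed=7)           # 4 chains x 1000 kept, 1000 warmup
print(diagnose(draws).table.round(4).to_string())

calls = call_sample(sim.counts, draws, threshold=0.99)
table = concordance_by_genotype(calls, sim.truth_map(), min_depth=10)
print(table.to_frame().to_string(index=False))
```

prints

```
               mean    ci_2.5   ci_97.5    rhat        ess
parameter
theta[0]     0.5858    0.5572    0.6168  1.0091   595.2920
theta[1]     0.2466    0.2213    0.2755  1.0084   535.0756
theta[2]     0.1676    0.1450    0.1916  1.0057   411.3450
mu[0]        0.0021    0.0015    0.0028  1.0043   719.2677
mu[1]        0.4663    0.4493    0.4840  1.0026   991.5516
mu[2]        0.9977    0.9964    0.9988  1.0016   909.7906
kappa[0]   500.3294  459.2827  545.5136  1.0040  1019.9468
kappa[1]    21.0446   16.2693   26.3975  1.0024   842.3896
kappa[2]    499.8533  459.7855  542.8168  1.0040   958.4281
truth_genotype  concordant  discordant  missing  accuracy
             0        2376           0       12  1.000000
             1         995           1        6  0.998996
             2         609           0        1  1.000000
           all        3980           1       19  0.999749
```

The learned heterozygote mean (0.466, truth 0.48) sits below 0.5 and its
concentration (≈ 21) is far from binomial — the ASE/mapping-bias signature
the model exists to absorb. At the 0.99 threshold, 3980 of 4000 sites are
hard-called with a single discordance; the 19 ambiguous sites are left
missing rather than guessed.

The same workflow is available from the shell:

```
betacall simulate --n-sites 4000 --seed 7 --out-dir sim/
betacall fit --counts sim/counts.tsv --train-size 1000 --seed 7 --out model.json
betacall call --counts sim/counts.tsv --model model.json --out-dir calls/
betacall benchmark --calls calls/calls.tsv --truth sim/truth.tsv --out-dir bench/
```

`fit` accepts `--min-eaf` (strict > cutoff on effect allele frequency) and
`--exclude-bed` (0-based half-open regions of known mapping bias) to filter
sites, and `call` can reuse a `model.json` fitted on any other sample of the
same study.

## Documentation

See `docs/methods.md` for the full model description, parameter meanings and
defaults, what the simulator does and does not emulate, and numerical
choices.
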