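# snpmix

Semi-nonparametric mixture screening of protein-microarray probes.

## The problem

On a protein microarray the probes are themselves proteins, and a probe is
only useful if it keeps its three-dimensional structure and binding
orientation after being spotted. Probes that lose structure — *functionally
inconsistent* proteins — report irreproducible abundances and inflate the
error rates of any downstream biomarker analysis, so they have to be
screened out before the array is used. Chemical validation is expensive;
`snpmix` does the screening statistically from a repeated, balanced
reference-design experiment.

## The method

For each protein the normalized log2 sample/reference ratios follow a
balanced ANOVA

    Y_ijkl = μ + T_j + S_k(j) + δ_ijk + ε_ijkl ,

with experiments *i*, patient groups *j*, patients *k*, on-array replicates
*l*. The between-array error δ (variance σ²_δ) and within-array error ε
(variance σ²_ε) are the random-error strata, and the per-protein
*consistency statistic*

    z = σ̂²_δ + σ̂²_ε

is small for reliable probes and inflated for damaged ones. The collection
z₁…z_m is modelled as a two-component mixture

    f(z) = λ₀ f₀(z|θ₀) + λ₁ f₁(z|θ₁) ,   mean(f₀) ≤ mean(f₁),

whose components are semi-nonparametric (SNP) densities — a squared
truncated Hermite polynomial times a Gaussian kernel, with truncation order
K ∈ {0, 1, 2} (K = 0 is exactly normal; higher K admits skewness, heavy
tails and bimodality). The mixture is fitted by an EM algorithm whose
M-step is a Newton-like step on the expected complete-data log-likelihood
with Davidon rank-one quasi-Newton acceleration; K is chosen by AIC/BIC/HQ;
whether two components are separable at all is decided by a parametric
bootstrap likelihood-ratio test. Each protein then gets a posterior
probability of inconsistency, from which the false discovery rate (FDR) and
false non-discovery rate (FNR) of any declaration cutoff are estimated and
a cost-minimizing cutoff is chosen:

    cost(d) = γ·FDR̂·d/m + (1−γ)·FNR̂·(m−d)/m .

See `docs/methods.md` for the full model account and design choices.

## Worked example

```python
from snpmix import (ArrayDesign, NoiseSpec, simulate_dataset,
                    consistency_stats, bootstrap_lrt, posteriors,
                    min_cost_threshold, FitConfig, GAMMA_COST_2TO1)

out = simulate_dataset(ArrayDesign(), NoiseSpec(), seed=42)   # 300 proteins, 150 damaged
stats = consistency_stats(out.table)
lrt, sel = bootstrap_lrt(stats.z, "bic", B=100, cfg=FitConfig(seed=1), seed=1)
print(f"LRT stat = {lrt.stat:.1f}, p = {lrt.p_value:.3f}, K = {sel.best_alt_K}")
post = posteriors(sel.best_alt, stats.z)
res = min_cost_threshold(post, gamma=GAMMA_COST_2TO1)
print(f"declared inconsistent: {res.d}, FDR^ = {res.fdr_hat:.3f}, FNR^ = {res.fnr_hat:.3f}")
```

prints (exact numbers depend only on the seeds):

```
LRT stat = 159.0, p = 0.010, K = (0, 1)
declared inconsistent: 147, FDR^ = 0.008, FNR^ = 0.115
```

i.e. the bootstrap test rejects a single component (p = 0.010, the smallest
attainable p-value at B = 100 is 1/101), and the 2:1-cost cutoff declares
147 of 300 proteins inconsistent — close to the 150 actually damaged by the
generator — with small estimated error rates.

The same pipeline is available from the shell:

```sh
snpmix simulate --seed 42 -o data.tsv --truth truth.tsv
snpmix run data.tsv -o results/ --boot 100 --cost-ratio 2:1 --seed 1
```

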