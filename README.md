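# informedbf

One-sided informed Bayes factors for correlation tests and t-tests, with
prior-sensitivity analyses over databases of studies.

## The problem

When experts translate their domain knowledge into prior distributions on an
effect size, different experts produce different priors — and unlike posterior
distributions, the Bayes factor stays sensitive to that choice no matter how
much data accrue. This package provides the machinery to quantify that
sensitivity: it computes one-sided Bayes factors for many hypothesis tests
under a panel of priors (six expert-elicited priors per test family, plus
defaults) and summarizes how often the priors agree on the direction of
evidence, on the evidence category, and by how much the Bayes factors
themselves differ.

## The model

For a test with data $\mathcal{D}$ the Bayes factor is the ratio of
prior-weighted marginal likelihoods

$$\mathrm{BF}_{10} = \frac{\int p(\mathcal{D}\mid\theta)\,\pi(\theta)\,d\theta}{p(\mathcal{D}\mid\theta_0)},$$

with a point null at $\rho = 0$ (correlations) or $\delta = 0$ (t-tests).

* **Correlation tests** use the exact reduced likelihood of the sample
  correlation $r$ under bivariate normality (nuisance means and variances
  integrated out), giving the likelihood-ratio kernel
  $k(\rho) = (1-\rho^2)^{(n-1)/2}(1-\rho r)^{-(n-3/2)}\,
  {}_2F_1(\tfrac12,\tfrac12;n-\tfrac12;\tfrac{1+\rho r}2)\,/\,
  {}_2F_1(\tfrac12,\tfrac12;n-\tfrac12;\tfrac12)$,
  so $\mathrm{BF}_{10} = E_\pi[k(\rho)]$. Priors on $\rho\in[0,1]$: six
  elicited beta distributions and the uniform default.
* **t-tests** use the noncentral-t density ratio
  $g(t;\nu,\delta\sqrt{n_\mathrm{eff}})/g(t;\nu,0)$ with
  $\nu = n_1-1,\ n_\mathrm{eff}=n_1$ for one-sample/paired designs and
  $\nu = n_1+n_2-2,\ n_\mathrm{eff}=n_1 n_2/(n_1+n_2)$ for independent
  samples. Priors on $\delta>0$: six elicited shifted-scaled t
  distributions truncated to positive effects and the positive-only
  Cauchy($0,\sqrt2/2$) default.

Marginalization is adaptive quadrature on the log scale; a seeded
Monte-Carlo prior-predictive average serves as an independent oracle in the
test suite. The elicitation side implements the histogram (roulette) method:
a parametric prior is fitted by least squares to chip proportions on a
ten-bin grid. Seeded generators produce synthetic study databases with the
structure of large meta-analytic collections (855 records; correlation
sample sizes 10–500; t-test designs mixed 85/604/166 with median per-group
n of 24), so the full pipeline runs without any external data.

## Worked example

```python
from informedbf import corr_bf10, bf_ratio, posterior_prob_h1, expert_registry

reg = expert_registry()
bf4 = corr_bf10(0.3, 260, reg["Expert 4 (beta)"])   # Beta(10.70, 22.98) prior
bf6 = corr_bf10(0.3, 260, reg["Expert 6 (beta)"])   # Beta(8.65, 12.39) prior
print(f"BF10 (Expert 4): {bf4.bf10:.0f}")
print(f"BF10 (Expert 6): {bf6.bf10:.0f}")
print(f"ratio: {bf_ratio(bf4, bf6):.2f}")
print(f"P(H1 | data), Expert 4: {posterior_prob_h1(bf4.bf10):.6f}")
```

prints

```
BF10 (Expert 4): 110138
BF10 (Expert 6): 60421
ratio: 1.82
P(H1 | data), Expert 4: 0.999991
```

For a correlation of 0.3 in a sample of 260 both experts find overwhelming
evidence for a positive correlation; their Bayes factors differ by ~50,000
in absolute terms, yet the ratio shows the data are only about twice as
likely under Expert 4's prior — the absolute difference is practically
irrelevant, which is exactly the kind of conclusion the sensitivity
analyses are built to make explicit.

The full pipeline runs from the command line:

```sh
informedbf synth --kind correlation --seed 1 --out db.csv
informedbf bf --input db.csv --schema correlation --out bfs.csv
informedbf sensitivity --bf-table bfs.csv --outdir results/
informedbf run-all --config config.yaml
```

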