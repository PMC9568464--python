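# Methods

## Hypothesis-testing framework

All tests are one-sided null-hypothesis comparisons: the null model places a
point mass at zero effect (Pearson $\rho = 0$ or Cohen's $\delta = 0$), the
alternative places a prior on positive effects, and the Bayes factor
$\mathrm{BF}_{10}$ is the ratio of the two marginal likelihoods. Because the
null is nested at a single point, the Bayes factor reduces to the
prior-expected likelihood ratio kernel, which is what the engine computes.

### Correlation tests

The likelihood of an observed sample correlation $r$ from $n$ bivariate
normal pairs, with the means and variances integrated out under standard
reference priors, depends on $\rho$ only through

$$k(\rho) = (1-\rho^2)^{\frac{n-1}{2}} (1-\rho r)^{-(n-\frac32)}
\frac{{}_2F_1\!\left(\frac12,\frac12;n-\frac12;\frac{1+\rho r}{2}\right)}
     {{}_2F_1\!\left(\frac12,\frac12;n-\frac12;\frac12\right)},$$

normalized so that $k(0) = 1$; hence $\mathrm{BF}_{10} = E_\pi[k(\rho)]$.
This is the exact finite-sample form, not a Fisher-z or large-sample
approximation, and it is asymmetric in $r$ exactly as the sampling
distribution of $r$ is. It requires $n \ge 4$ and $|r| < 1$.

### t-tests

For a t statistic the kernel is the noncentral-t density ratio
$g(t;\nu,\delta\sqrt{n_\mathrm{eff}})/g(t;\nu,0)$. Design conventions:
one-sample and paired tests use $\nu = n_1 - 1$, $n_\mathrm{eff} = n_1$
(a paired test is a one-sample test on difference scores, so only $n_1$ is
used; rows that report a second, different group size for a paired design
are flagged by the validator rather than dropped); independent-samples
tests use $\nu = n_1 + n_2 - 2$ and $n_\mathrm{eff} = n_1 n_2/(n_1+n_2)$.

## Prior families and registry

Six elicited beta priors on $\rho \in [0,1]$ and six elicited shifted-scaled
t priors on $\delta$ (truncated to $\delta > 0$) are built in, one pair per
expert, together with the defaults — uniform(0, 1) on $\rho$, positive-only
Cauchy with scale $\sqrt2/2$ on $\delta$ — and the two point nulls. The
beta priors are taken on $[0,1]$ directly: the elicitation targets a
one-sided question (an effect in the hypothesized direction), so no
stretching to $(-1,1)$ is applied. Truncated families are renormalized by
the untruncated upper-tail mass at zero; every non-point prior integrates
to 1 within $10^{-6}$ (tested).

## Numerics

* All marginalization is performed on the log scale. A 513-point grid over
  the (transformed) support locates the integrand's maximum; the shifted
  integrand is then integrated by adaptive Gauss–Kronrod quadrature
  (`scipy.integrate.quad`, absolute/relative tolerance $10^{-10}$, limit
  300 subintervals). The half-line $\delta \in (0,\infty)$ is mapped to
  $(0,1)$ via $u = \delta/(1+\delta)$.
* Very large Bayes factors are represented by `log_bf10`; the natural-scale
  value saturates to `inf` rather than raising.
* The noncentral-t density is evaluated through scipy's closed form. Many
  standard deviations into the tail (large $\nu$ combined with large
  noncentrality) that routine can overflow or return nan; those elements
  are recomputed with a Gaussian moment-matched tail approximation. The
  patch only ever applies where the density is negligible relative to the
  integrand's peak (log densities around −200 and below), so marginal
  likelihoods are unaffected at the stated tolerances.
* A seeded Monte-Carlo oracle (prior draws by inverse-CDF, kernel averaged
  with a log-shift) provides an independent estimate with a standard error;
  the suite requires quadrature and oracle to agree within 3 standard
  errors at $10^5$ draws for every registry prior over a grid of inputs.
* Point priors bypass quadrature entirely (the integral is the kernel at
  the point).

## Elicitation fitting

The histogram (roulette) method is modeled as a ten-bin grid on $[0,1]$
with at most ten chips per bin. Fitting minimizes the sum of squared
differences between chip proportions and the family's bin probabilities
(CDF differences across the bin edges, renormalized to the grid range),
via bounded L-BFGS-B from moment-based start values. Degrees of freedom are
unconstrained reals in $[0.5, 500]$ during fitting. Grids occupying fewer
bins than the family has parameters yield an under-determined-fit warning
and a best-effort result. On noiseless expected-count grids the fit
recovers beta, truncated-normal and truncated-t parameters well within 15%
(tested); real elicitations quantize chips to integers and cap bins at ten,
which degrades recovery for very peaked priors — the deterministic grid
generator produces fractional expected counts precisely to separate fitting
error from quantization error.

## Synthetic databases

The generators emulate the two kinds of meta-analytic databases the
pipeline is designed for, so that every stage is testable without
downloading external data.

* **Correlations**: 855 studies; $n$ log-uniform on [10, 500]; effects from
  a two-component mixture of 50% exact nulls and 50% draws from a
  Beta(2, 5) population of correlations. The mixture proportion of real
  databases is unknowable, so 50% is a neutral, configurable choice; with
  it the synthetic median $r \approx 0.11$, close to the ~0.15 typical of
  such collections. $r$ is computed from actually simulated bivariate
  normal pairs — not by sampling the analytic $r$ density — so the
  generator cannot inherit an error from the engine's likelihood.
* **t-tests**: 855 studies in the 85/604/166 one-sample/paired/independent
  mix (largest-remainder apportionment, order shuffled); per-group $n$ on
  [2, 212] from a two-piece log-uniform with half the mass on each side of
  24, so the population median hits the target exactly; $t$ built exactly
  as $(Z + \delta\sqrt{n_\mathrm{eff}})/\sqrt{\chi^2_\nu/\nu}$.
* What the generators do **not** reproduce: the skewness of real
  sample-size distributions, journal composition, and the extreme
  sample-effect tails (|d| > 4 at tiny $n$). Consequently, passing
  pipeline tests demonstrate internal correctness and the qualitative
  agreement patterns, not the exact agreement rates of any real database.

## Sensitivity analyses

* **Direction agreement**: fraction of studies where both Bayes factors are
  strictly on the same side of 1. A BF exactly equal to 1 counts as
  disagreement (measure-zero; fixed for determinism).
* **Category agreement**: fraction of studies in the same evidence
  category. Default scheme: strong H1 above 10, strong H0 below 1/10,
  inconclusive between, with strict inequalities at the bounds; a
  six-category Jeffreys-style scheme (edges 1/10, 1/3, 1, 3, 10) is also
  provided. "Strong vs inconclusive" and "strong vs opposite-strong" both
  count as disagreement; the latter event additionally gets a dedicated
  flag-level check in the suite because it should essentially never occur.
* **Ratios**: per-study quotients of Bayes factors for each ordered prior
  pair — themselves Bayes factors between the two alternative models —
  summarized by quantiles and the fraction within [1/3, 3].

## Design choices and limitations

* The pairwise agreement matrices require a complete study × prior grid;
  records failing engine preconditions are skipped with a logged reason and
  counted in the run manifest rather than silently dropped.
* Correlation-database filtering applies the three hygiene rules in a fixed
  order (perfect correlations; unequal/non-integer sample sizes; $n$
  outside [10, 500]) and reports per-rule removal counts sequentially.
* The predictive-accuracy property (a prior matched to the data-generating
  effect attains a higher median log BF than mismatched priors) is asserted
  against priors whose mode differs by at least 0.2 from the matched one;
  two of the elicited t priors are nearly identical (modes 0.59 vs 0.60),
  and between near-duplicates the ordering of finite-sample medians is not
  statistically guaranteed.
* Exact reproduction of published database-level agreement rates is out of
  scope: it requires the original proprietary databases and their original
  subsampling, neither of which is bundled.
* Problem sizes in the test suite (855-study synthetic databases for the
  agreement pattern, $10^5$ oracle draws, 300–4000-study generator checks)
  are the package's chosen verification scale; all are configurable.
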