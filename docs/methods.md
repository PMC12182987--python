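# Methods

## Model

A structural connectivity value $c \ge 0$ for one region pair, across the
subjects of one site, is modeled as a zero-inflated gamma (ZIG) mixture: an
atom at zero with weight $\lambda \in [0,1]$ and a gamma density with scale
$\beta > 0$ and shape $\gamma > 0$ on the positive part. The zero atom
captures region pairs with no direct anatomical pathway in a subset of
subjects; the gamma captures the skewed, unbounded-above positive values that
tractography-derived connectivity produces. Connections are modeled
marginally and independently — no inter-connection covariance is estimated or
used.

The mixture CDF uses a step with $u(0) = 0$, so $F(0) = 0$ exactly. This is
the design choice that makes the quantile-mapping transform zero-preserving:
a zero has percentile 0, and the reference inverse CDF sends any percentile
$p \le \lambda_R$ to 0. The opposite convention ($u(0)=1$, under which zeros
may become positive at a denser reference site) is implemented behind
`preserve_zeros=False` and is off by default: sparsity of a connectome is
physically meaningful, and silently densifying it complicates
interpretation.

## Estimation

Per connection, per site (and per sex group under stratification):

- $\lambda$ is the empirical fraction of *exact* zeros. No epsilon threshold
  is applied — zero tract counts are exact zeros, and thresholding would
  silently change $\lambda$.
- $(\beta, \gamma)$ are the maximum-likelihood estimates over the strictly
  positive values (`scipy.stats.gamma.fit` with location fixed at 0). The
  shape is not constrained to $\gamma \ge 1$; when $\hat\gamma < 1$ (density
  diverging at the origin) a warning is emitted rather than the estimate
  being clipped, since a constrained fit would bias the quantile map.
- A fit with fewer than `min_nonzero` positive values (default 10) is
  flagged unreliable. A connection whose reference or new-site fit is
  unreliable is mapped by the identity ("passthrough") rather than aborting
  the run; the model records a manifest of such connections. With one
  positive value the MLE is undefined and a degenerate (shape 1, scale equal
  to the value) placeholder is recorded, always flagged unreliable.

## The transform

Harmonization maps each new-site value to the reference value of equal
percentile, $T_{N\to R} = F_R^{-1} \circ F_N$. Fitting and mapping happen on
$\log(1+c)$ by default: the log damps the heavy tail and stabilizes the
gamma MLE, and zeros are invariant under $\log(1+\cdot)$, so $\lambda$ is the
same in either space. The log is undone with $e^c - 1$ after mapping.
`log_space=False` switches both fitting and mapping to raw values.

Numerical choices:

- The composition is evaluated in a fused form. Writing
  $q = G_{\beta_N,\gamma_N}(c)$, the inner argument of the reference gamma
  quantile is computed as
  $(\lambda_N - \lambda_R)/(1-\lambda_R) + q\,(1-\lambda_N)/(1-\lambda_R)$
  rather than $(F_N(c) - \lambda_R)/(1-\lambda_R)$. The two are algebraically
  identical, but the latter cancels catastrophically when $q$ is below the
  floating-point resolution of $\lambda$ (values deep in the gamma lower
  tail), which would spuriously send small positive values to zero. With the
  fused form, self-harmonization is the identity on nonzeros to ~1e-13
  relative error.
- Probabilities entering a gamma quantile are clipped at $1 - 10^{-12}$, so
  outputs are finite even for a value at the extreme of its fitted
  distribution.
- A nonzero maps to zero exactly when $F_N(c) \le \lambda_R$, i.e. only when
  the reference site is sparser than the new site; those are the smallest
  values of the connection, preserving monotonicity.

Under sex stratification, a stratum present in the new site but absent from
the reference is an error: there is no reference distribution to map onto,
and silent pooling would contaminate the strata.

### Covariate residualization

For a continuous covariate $x$ (e.g. age), `residualize_covariate` fits the
per-connection slope $\alpha$ of $c$ on $(x - \bar x)$ by least squares
within each site and returns $\tilde c = c - \alpha(x - \bar x)$ plus the
slope table. Residuals may dip below zero; the function does not clip them
(so least-squares orthogonality holds exactly) and leaves both clipping and
possible restoration of the effect after harmonization to the caller. Do not
residualize on a covariate that is itself the downstream outcome variable —
that leaks the outcome into the harmonization.

## Augmentation

Augmented connectivity adds indirect (multi-synaptic) pathway strength: the
subject's matrix is treated as a resistor network with edge conductance equal
to direct connectivity, and the augmented value of a pair is its effective
conductance $1/R_{\mathrm{eff}}$, computed from the graph-Laplacian
pseudoinverse per connected component
($R_{\mathrm{eff}}(i,j) = L^+_{ii} + L^+_{jj} - 2L^+_{ij}$). Disconnected
pairs get 0 (no current path). The computation is isolated behind one
function so a different augmentation rule can be swapped in. No normalization
or capping is applied to the effective conductances. Because harmonization
must operate on original connectivity (zeros are only meaningful there),
the intended pipeline is: harmonize original values, then re-augment.

## Evaluation battery

- **Bounded transform** $c \mapsto 1 - e^{-c/\bar c}$ per connection
  ($\bar c$ the cross-subject mean) confines values to $[0, 1)$ before
  correlation, for robustness to the heavy tail. All-zero connections stay
  zero.
- **Correlation screen**: Pearson $r$ and two-sided $p$ per connection
  against a covariate; subjects with a missing covariate are dropped;
  zero-variance connections are recorded as missing and excluded from
  summaries and from the Bonferroni factor, which is the number of
  connections actually tested in the run (3570 for 85 regions), never a
  hard-coded constant. Significance is $s = -\log p$ in natural log; any
  fixed base would only rescale $\Delta s$, so rankings are base-invariant.
- **Method comparison**: one-sided Wilcoxon signed-rank on paired $|r|$
  (alternative: harmonized $>$ baseline), zero differences discarded before
  ranking — the common convention. The test assumes symmetry of the paired
  differences, which connectivity data need not satisfy; its p-values should
  be read with that caveat. All-zero differences are a degenerate case
  reported as $p = 1$ with a warning. The summary carries mean and SD of
  $|r|$, the Wilcoxon p, the count of connections with Bonferroni-corrected
  $p < 0.05$, the minimum corrected p, and per-connection $\Delta s$.
- **$\Delta s$ ranking** selects connections at requested quantiles of
  $\Delta s$ (default min, 25th, median, 75th, max) under the nearest-rank
  rule, ties broken by connection index.
- **Subsampling stability** refits the ZIG model on `n_perm` random subsets
  of one connection's sample (without replacement, seeded generator) and
  returns all fits plus the full-sample fit, quantifying the estimation
  variability a smaller cohort introduces.

## Synthetic data

The generator draws, per connection, zeros with probability $\lambda$ and
log-space positive values from gamma$(\gamma, \beta)$, adds linear covariate
effects $\alpha(x - \bar x)$ in log space, floors log values at $10^{-9}$
(covariate shifts could otherwise push them negative), and exponentiates
with $e^c - 1$. Covariate effects act in log space because that is where the
pipeline fits distributions and residualizes — generator and model
assumptions are aligned by construction, so parameter recovery and
end-to-end tests are exactly specified. Consequences worth keeping in mind:
real connectomes have spatially structured, correlated connections, site
effects that need not be a clean $(\lambda, \beta, \gamma)$ shift, and
covariate effects that need not be linear in log space; passing tests
demonstrate correctness of the method under its own assumptions, not
robustness to their violation.

The default two-site study (`default_study_specs`) uses 21 regions (210
connections), 300 reference and 150 new-site subjects — enough subjects for a
stable per-connection gamma MLE while keeping the full pipeline at
seconds-scale — with per-connection parameters drawn uniformly
($\lambda \in [0.05, 0.3]$ vs $[0.15, 0.4]$; $\beta \in [0.3, 0.6]$ vs
$[0.7, 1.2]$, i.e. roughly a doubled scale; shape $\in [2, 4]$ at both
sites), and a standardized covariate with effect 0.3 on the first 20
connections shared by both sites. The acceptance script and the end-to-end
tests run at these sizes.

## Known limitations

- Percentile mapping transfers the reference site's distribution exactly
  only as both sites' sample sizes grow; at small $n$ (the subsampling
  analysis quantifies this) the fitted transform is noisy, and harmonizing a
  small new site can degrade rather than help.
- The ZIG model is marginal per connection; joint structure across
  connections is untouched, so covariance-level site effects (the target of
  CovBat-style methods) are out of scope.
- Multi-site runs are pairwise: each new site is harmonized to the reference
  independently.
- The Wilcoxon comparison p-values inherit the symmetry caveat above.
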