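# Methods

This note documents the statistical model, the sampler, the derived
quantities, and every numerical or conventional choice a user may need to
know to interpret results or reproduce them elsewhere.

## 1. Data model

### 1.1 Densities and growth rates

Surveys record captures `c` and effort `e` (trap-nights) per location-year.
The standardized density rescales to the reference protocol of 150
trap-nights (50 snap traps × 3 nights):

```
Z = c · 150 / e
```

The yearly population growth rate is

```
Y_t = (Z_t − Z_{t−1}) / (1 + Z_{t−1})
```

the fractional change of `1 + Z`. The unit shift keeps the rate finite when a
year records zero captures; `log(1+Z_t) − log(1+Z_{t−1})` is its first-order
approximation. Growth rates are only defined when the immediately preceding
calendar year was surveyed; gaps split a series into contiguous runs.

Assumptions: captures scale linearly with effort (no saturation), and the
survey protocol is comparable across locations. Records with non-positive
effort are rejected with a warning; negative captures and duplicate
(location, year) records are hard errors.

### 1.2 Hierarchical panel AR(p)

For locations `k = 1..m` and years `t`:

```
Y_kt = θ_0k + Σ_{j=1..p} θ_jk Y_{k,t−j} + η_t + e_kt
e_kt ~ N(0, 1/τ_k)
log(1/τ_k) = log(1/τ) + ζ_k,  ζ_k ~ N(0, σ²_τ)
η_t ~ N(0, σ²_η)              (shared across locations within a year)
θ_k = μ + ε_k,  ε_k ~ N(0, ξ I)
```

Priors: `1/τ ~ IG(a, b)`, `σ²_τ ~ IG(a_σ, b_σ)`, `σ²_η ~ IG(a_η, b_η)`,
`ξ ~ IG(a_ξ, b_ξ)`, `μ ~ N(u, V)`, and `p(p) ∝ 1/(p+1)!` on `1..p_max`.

Defaults (all overridable via `ModelSpec`): every inverse-gamma
hyperparameter `0.01` (diffuse), `u = 0`, `V = 100 I`, `p_max = 5`, proposal
decay `λ = 1`. The diffuse IG defaults have no finite prior moments; they are
fine for data analysis but distributional validation (the prior-recovery
test) uses proper informative settings such as `IG(3, 2)`.

**Conditioning convention.** The likelihood conditions on the first `p_max`
observations of every contiguous run, for *every* candidate order. All
orders therefore score exactly the same response set, which makes the
conditional order posterior comparable across orders inside the
reversible-jump move. Locations whose runs are all shorter than `p_max + 1`
contribute no rows and are dropped with a warning.

## 2. Sampler

One sweep updates, in this order:

1. **AR order `p`** — reversible jump (below);
2. **`μ`** — Gibbs, with every `θ_k` integrated out;
3. **`θ_k`** — Gibbs, `N(P⁻¹h, P⁻¹)` with `P = I/ξ + τ_k XᵀX`,
   `h = μ/ξ + τ_k Xᵀ(Y − Zη)`;
4. **`η`** — Gibbs; each observation row maps to one calendar year, so the
   precision is diagonal and the draw factorizes per year;
5. **`σ²_τ, σ²_η, ξ`** — conjugate inverse-gamma draws;
6. **`τ`, then each `τ_k`** — independence Metropolis–Hastings.

The `τ`-before-`τ_k` order within a sweep is a fixed convention; any order
leaves the stationary distribution invariant.

### 2.1 Marginalized order move

The proposal is `q(p → p′) ∝ exp(−λ|p′ − p|)` normalized over `1..p_max`
(self-moves allowed). Because the normalizer depends on the current order
near the boundaries, the acceptance ratio keeps the exact `q`-ratio.

The target ratio uses `p(p | Φ⁻, Y)` with `μ` and all `θ_k` integrated out.
Writing `W_k = Y_k − Z_k η`, the stacked `W` is Gaussian with mean `X_k u`
and covariance

```
Cov(W_k, W_j) = X_k V X_jᵀ + δ_kj (ξ X_k X_kᵀ + I/τ_k).
```

Evaluation is by two nested applications of the matrix-inversion lemma: the
block-diagonal part per location with `G_k = I/ξ + τ_k X_kᵀX_k`
(`log|A_k| = −n_k log τ_k + log|G_k| + (p+1) log ξ`), the rank-(p+1)
shared-`μ` coupling with `M = V⁻¹ + Σ_k X_kᵀ A_k⁻¹ X_k`. Cost is
`O(Σ_k n_k (p+1)²)` per candidate order. On acceptance, `(μ, θ)` are
refreshed by immediate Gibbs draws at the new dimension, completing the
trans-dimensional move.

This closed form is validated in the test suite against brute-force
Gauss–Hermite quadrature over `(μ, θ)` and against a dense construction of
the joint Gaussian evaluated with `scipy.stats.multivariate_normal`.

### 2.2 `μ` with `θ` integrated out

Marginally `W_k ~ N(X_k μ, I/τ_k + ξ X_k X_kᵀ)`, so

```
precision  A = V⁻¹ + Σ_k [ I/ξ − G_k⁻¹/ξ² ]
rhs        b = V⁻¹u + Σ_k (τ_k/ξ) G_k⁻¹ X_kᵀ W_k
```

using the identity `X_kᵀ(I/τ_k + ξX_kX_kᵀ)⁻¹X_k = I/ξ − G_k⁻¹/ξ²`.

### 2.3 Precision hierarchy

`τ`: the independence proposal is `log(1/τ′) ~ N(mean_k log(1/τ_k), σ²_τ/m)`.
The normal factor and Jacobian cancel between target and proposal and the
Hastings ratio reduces to a ratio of `Gamma(a+1, rate b)` densities:
`log r = a(log τ′ − log τ) − b(τ′ − τ)`.

`τ_k`: proposal `log(1/τ_k′) ~ N(log(1/τ), σ²_τ)`; the hierarchy factor
cancels and `log r = (n_k/2)(log τ_k′ − log τ_k) − (SSR_k/2)(τ_k′ − τ_k)`.

Both reductions are verified in the tests against the general
target/proposal ratio computed from the unreduced densities (identical
trajectories on a shared random stream).

### 2.4 Numerical choices

- Cholesky factorizations get one retry with `1e-10` jitter on the diagonal;
  a second failure aborts the chain.
- A non-finite parameter aborts the run with a state dump naming the
  offending block and iteration.
- Traces store order-varying vectors NaN-padded to `p_max + 1`; CSV output
  uses 17 significant digits (`%.17g`) so files round-trip exactly.
- Default run lengths: 50 000 iterations, 10 000 burn-in, thinning 5. Tests
  and the acceptance script use much shorter, explicitly-passed runs sized
  for their panels.

## 3. Clustering

Pairwise dissimilarity between growth-rate series over shared years:
`d = 1 − r` when the Pearson correlation is significant (two-sided,
`α = 0.05`), else `d = 1`; pairs must share ≥ 3 years; constant series fall
back to `d = 1` with a warning.

Agglomeration is Ward's minimum-variance criterion via the Lance–Williams
recurrence applied to the **raw** dissimilarities — the `ward.D` convention
(some libraries square distances first, the `ward.D2` convention, which
yields different trees). Ties in the minimum pairwise distance break to the
smallest (id_i, id_j) pair, so results are deterministic. The implementation
is self-contained precisely because common library routines fix the other
convention and an uncontrollable tie rule; it is validated against a frozen
hand computation on a 5-leaf instance.

**Cut rule.** Every cluster owns a vertical branch from its formation height
to the height where it next merges. The rule finds the longest such branch
anywhere in the dendrogram and cuts at the largest multiple of 0.1 strictly
below that branch's merging point; ties prefer the lower merging point, then
the lower cluster id. When several dendrograms are cut together, the common
height is the maximum of the per-dendrogram rule heights.

## 4. Cycle structure

A stationary AR(p) has characteristic polynomial
`z^p − θ_1 z^{p−1} − … − θ_p`. Each complex pair `r e^{±iω}` contributes a
quasi-cycle of period `2π/ω` years damped by `r` per year; a real positive
root contributes pure exponential decay; any root modulus ≥ 1 means
nonstationarity. For AR(2) with complex roots the closed form is
`T = 2π / arccos(θ_1 / (2√(−θ_2)))`. Posterior uncertainty propagates by
root-finding per retained draw. Roots with `|Im| ≤ 1e-9` are treated as real.

## 5. Synthetic data and validation

`simulate_panel` draws from the exact generative model (coefficients,
precision hierarchy, yearly effects, then the AR recursion after a discarded
warm-up of 100 + p steps). An optional count layer maps growth rates to
densities from a baseline offset — clipping at zero, since densities cannot
be negative — and draws Poisson captures given effort, so preprocessing can
be exercised end to end. The generator does **not** emulate observation
artifacts beyond Poisson sampling (no trap saturation, missed surveys, or
species misidentification), and the clipped density link is only used for
count generation, never in inference.

Validation layers, in increasing integration:

1. every conditional against dense grids of an independently composed joint
   posterior (tiny fixed instance, deterministic);
2. the marginalized order posterior against quadrature;
3. the full sampler against its own prior by successive-conditional
   simulation (alternating parameter sweeps with data redraws; retained
   parameter marginals must match the prior, checked by KS). This uses a
   small panel (m = 4, n = 7) and thinning 30 because the
   successive-conditional chain is autocorrelated — the data carry parameter
   memory between sweeps — and the KS test assumes independent draws;
4. order recovery and credible-interval coverage on replicated synthetic
   panels (`simulation_study`).

## 6. Diagnostics

Geweke's z compares the mean of the first 10% of a chain with the last 50%,
standardized by spectral-density-at-zero standard errors (Bartlett window,
automatic truncation `L = floor(4 (n/100)^{2/9})`), so autocorrelation
inflates the denominator appropriately. Chains shorter than 100 draws report
NaN. Posterior summaries condition order-varying parameters on the modal
order so one coherent coefficient set is reported per fitted panel.
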