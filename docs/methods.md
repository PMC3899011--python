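# Methods

## Model

Genes responding to a toxin-induced malignant transformation are
partitioned into a driver set of fixed size `d` (active in every
independently transformed isolate), a passenger set of size `T` whose
members are active in any given isolate independently with probability
`p`, and non-responsive genes. Writing `y_k` for the mean k-way
intersection of activated-gene sets over all subsets of `k` of the `n`
profiled isolates, independence gives `E[y_k] = d + T p^k`: the overlap
decays geometrically onto the driver count. On the log scale,
`log(y_k − d) = α + β k + ε` with `α = log T`, `β = log p`, and ε
assumed i.i.d. Gaussian.

Assumptions worth stating: passenger activations are independent across
genes *and* isolates (real passenger behaviour shows some non-random
structure, which this model deliberately ignores); the driver set is
identical in every isolate (no partially penetrant drivers); induced and
repressed responses are modelled separately and never coupled through
shared genes.

## The estimator

`d` enters the regression non-linearly, so it is profiled out by grid
search: for every integer `d` from 0 to the largest integer strictly
below `min(y)` (every candidate asymptote that keeps `y − d` positive;
for integer-valued curves this is `min(y) − 1`), ordinary least squares
of `log(y_k − d)`
on `k` is fitted in closed form, and the `d` maximizing adjusted
R² `= 1 − (1 − R²)(n−1)/(n−2)` is selected. Ties within `1e-12` resolve
to the smallest `d` (fewest drivers — the conservative choice; genuine
ties occur only on noiseless curves). Natural logs are used throughout;
the selection is invariant to the log base since R² is affine-invariant
(a test asserts base-10 agreement). Curve means are fitted at full
precision, never rounded first.

Two caveats on flat profiles. First, near its peak the adjusted-R²
profile can be extremely flat: on the six-point cadmium-induced curve
printed as `1673, 850, 574, 433, 346, 285`, the profile values at
d = 233 and d = 234 differ by under `1e-6`, so the selected integer is
sensitive to rounding of the input means (this package selects 234 on
that rounded curve). Second, `adj R²` compares fits across different
response vectors `log(y − d)`, which is a heuristic rather than a
likelihood comparison; it is kept because it is the method's defining
selection rule.

Derived quantities: `T̂ = exp(α̂)`, `p̂ = exp(β̂)`, predicted common-gene
count `d̂ + T̂ p̂^x` at any isolate count `x` (strictly decreasing to the
asymptote `d̂` when `p̂ < 1`; a warning is raised if a non-decaying fit
is used for prediction).

### Required number of isolates

The design question "how many isolates until the common set *is* the
driver set" is answered by scanning `x` upward and stopping at the first
`x` where the upper limit of the two-sided confidence interval for the
mean response — computed on the log scale with the Student-t quantile at
`n − 2` df, `SE(x) = σ̂ √(1/n + (x − x̄)²/Sxx)`, then exponentiated and
shifted by `d̂` — comes within `tol` of `d̂`. Defaults: 95% confidence,
`tol = 0.5` genes (the predicted count rounds to `d̂`). Both conventions
are package choices: the interval type (mean response vs prediction),
the scale, the quantile family and the threshold are all configurable
because no single convention is canonical for this stopping rule, and
reasonable variants shift the answer by roughly one isolate. With zero
residual variance the interval collapses to the point prediction and the
rule reduces to `T̂ p̂^x < tol`.

### Four-parameter logistic comparator

`y = D + (A − D)/(1 + (x/C)^B)` fitted by bounded nonlinear least
squares (`D ≥ 0`; initialization `A₀ = y₁`, `D₀ = y_n`, `C₀ = median x`,
`B₀ = 1`). Its lower asymptote `D` is an informational cross-check on
`d̂`, never the estimate. On short, steeply decaying curves the 4PL
asymptote is poorly identified — on the printed cadmium curve the global
least-squares solution degenerates toward a hyperbola with `D ≈ 0` —
which is precisely why the grid-search estimator, not the 4PL, is the
method.

## Activation calls and overlap curves

A probe is called induced in an isolate when its intensity is at least
`threshold` times the arithmetic mean of the control samples, repressed
when at most `1/threshold`; the boundary is inclusive and the default
threshold is 2 (the conventional two-fold rule). Control means are
averaged on the raw intensity scale, not the log scale. Probes with
nonpositive or non-finite control means are dropped with a logged count
— a guard, since MAS5-style intensities are positive. Replicate arrays,
if present, are treated as separate call columns unless collapsed by the
caller.

The overlap curve is computed exactly via
`y_k = Σ_g C(m_g, k)/C(n, k)`, where `m_g` counts the isolates in which
probe g is active: a probe contributes to a k-subset's intersection iff
all k isolates are among its `m_g`. This avoids enumerating `C(n, k)`
subsets (the enumeration is kept as a test oracle) and guarantees
`y_1 = mean(per-isolate counts)` and `y_n = |full intersection|` to
machine precision.

## Overlap null test

The null model draws, for each isolate, a uniformly random probe subset
of the observed activated count and intersects them. Sampling is an
iterated hypergeometric chain — the intersection size after folding in a
subset of size `s` is `Hypergeometric(N, I_prev, s)` — vectorized across
repetitions (one vectorized draw per subset, in the order the sizes are
given), bit-reproducible per (seed, reps). A naive explicit-set sampler
is retained for verification, and the closed form
`E[overlap] = N Π(nᵢ/N)` anchors the simulation mean. Exceedance is
counted as simulated ≥ observed (conservative; identical to strict >
whenever the count is zero), and the p-value is reported both as the
add-one estimator `(b+1)/(reps+1)` and as the bound-style
`p ≤ (b+1)/reps` (`1/reps` when no draw reaches the observed value).

## Passenger simulation

For given `(T, p)` the minimum isolate count is simulated by thinning:
only the running-intersection size is tracked, and each surviving gene
survives the next isolate with probability `p`, so the size is a
binomial chain — distributionally identical to materializing full active
sets (the naive version is kept for tests). The count starts at `n = 1`:
the intersection over one isolate is its own active set, which can
already be empty. Each (T, p) cell of a sweep uses 10 replicates by
default, reporting mean and standard error, with per-cell RNG substreams
spawned from the master seed. A cap (default 10,000 isolates) guarantees
termination and raises an explicit error when reached (p = 1 never
empties). The closed-form CDF `P(min n ≤ k) = (1 − p^k)^T` is the test
oracle; its mean at `T = 5000` is 4.44, 8.05 and 13.62 isolates for
`p = 0.1, 0.3, 0.5`, so ten-replicate means typically round to 4–5, 8,
and 13–14 respectively — the `p = 0.1` and `p = 0.5` anchors straddle a
rounding boundary and their rounded value is seed-dependent.

## Synthetic generator

`generate_activation` draws the model exactly: drivers all-true,
passengers i.i.d. Bernoulli(p) per gene × isolate, non-responsive
all-false, with a disjoint probe-ID partition returned as ground truth.
Defaults mirror the case-study scale (six isolates). `p = 1` is handled
deterministically. `generate_expression` lifts calls to intensity space:
per-probe log-normal baselines (log-scale mean 6, SD 1 — arbitrary
units at microarray-intensity scale), three control samples with 0.1
log-SD scatter, and transformed values placed a multiplicative `margin`
(default 0.2) beyond the 2-fold boundary when called, strictly inside
the no-call band when not. The guaranteed contract is the round trip —
`call_activation(generate_expression(act)) == act` for any positive
margin — not distributional realism: probe-level noise, batch effects,
MAS5 summarization artefacts and correlated passenger activation are all
absent, so passing tests demonstrate estimator correctness under the
model, not robustness to real microarray noise.

`end_to_end_recovery` chains generator → exact overlap curve → grid
search and reports `d̂ − d`, `p̂`, `T̂` against truth. Under the model the
estimator is accurate at realistic scale: at `d = 200, T = 5000,
p = 0.3` with 10 isolates the median |d̂ − d| over 20 seeds is ~1 gene;
at the cadmium-fit scale (`d = 233, T ≈ 2472, p ≈ 0.53`, 6 isolates)
it is a few genes, and accuracy improves as isolates are added
(consistency is regression-tested from 4 to 12 isolates). `p̂` and `T̂`
are noticeably biased when `d̂` misses by even one gene on a short curve
(the log transform amplifies tail errors); only `d̂` is the headline
estimand.

## Numerical and problem-size choices

- Grid-search OLS uses the closed-form centered-data formulas; an
  independent statsmodels fit agrees to 1e-10 in tests.
- The million-repetition null test runs in ~1 s (vectorized chain);
  test-suite statistical checks use 2,000–50,000 draws with 3–4 SE (or
  Kolmogorov-distance / chi-square) tolerances and fixed seeds.
- Expectation checks of the generator use 50 seeds with a binomial SE
  floor `√(T p^k (1−p^k)/50)`, since the sample SE degenerates at deep
  k where the surviving-passenger count is almost surely zero.
- Degenerate inputs: curves with `min(y) < 1` (no valid asymptote
  candidate), fewer than 3 points, non-decaying fits in the
  sample-size rule, and a reached isolate cap all raise typed errors
  with actionable messages rather than returning NaNs.

## Limitations

- `d̂` carries no uncertainty statement beyond the adjusted-R² profile;
  the method itself provides none.
- Adjusted-R² selection across transformed responses is heuristic (see
  above); flat profiles make the integer argmax sensitive to input
  rounding.
- The required-isolate rule depends on an interval convention that is a
  package choice among several defensible ones.
- The generator does not emulate correlated passenger activation or
  array-level noise; conclusions about real arrays require real data.
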