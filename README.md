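# soflr

Estimate how many genes are *consistently* activated — induced or
repressed — across independently derived malignant transformations of the
same cell line by a single toxicant, from the expression profiles of only
a handful of transformed isolates.

## The problem and the model

When a parental cell line (for example the human urothelial line UROtsa)
is independently transformed several times by the same agent (Cd²⁺,
As³⁺), each isolate activates thousands of genes, but only some of that
response is reproducible. The genes split into three groups:

- a **driver set** of fixed size *d*, activated in every isolate (the
  downstream product of pathways hit by driver events);
- a **passenger set** of *T* genes, each activated in any one isolate
  independently with probability *p*;
- **non-responsive** genes, never activated.

Let *y_k* be the mean size of the k-way intersection of activated-gene
sets over all subsets of *k* isolates. Under the model

```
E[y_k] = d + T p^k        so        log(y_k − d) = α + β k + ε,
```

with `α = log T`, `β = log p < 0`, and ε Gaussian noise. *d* is the
asymptote: the number of genes that would still be shared by arbitrarily
many isolates. **SOFLR** (sequentially optimizing the fitting of linear
regression) estimates *d* by trying every integer `d` below `min(y)`,
fitting ordinary least squares of `log(y_k − d)` on `k`, and selecting
the `d` that maximizes adjusted R². The fitted line then gives
`T̂ = exp(α̂)`, `p̂ = exp(β̂)`, predictions `d̂ + T̂ p̂^x` for hypothetical
isolate counts *x*, and the smallest number of isolates at which the
predicted common-gene count collapses onto `d̂` (an experimental-design
quantity: how many independent transformations are worth profiling).

The package also provides

- **activation calling**: binary calls from an expression matrix (≥2-fold
  change against the control mean) and exact mean overlap-decay curves
  via the identity `y_k = Σ_g C(m_g, k) / C(n, k)`;
- a **Monte Carlo overlap null test**: is the observed all-isolate
  overlap larger than random, independent probe subsets of the same sizes
  would produce? (iterated hypergeometric chain sampler, O(#subsets) per
  draw);
- a **passenger simulation**: the minimum number of isolates until the
  passenger-only overlap vanishes, as a function of *T* and *p*;
- a **synthetic generator** for the full driver/passenger/non-responsive
  model, down to intensity matrices that round-trip through the
  activation caller.

The regression core is exposed as scikit-learn-style estimators
(`SOFLRRegressor`, `FourParamLogistic`, `ActivationCaller`) plus thin
functional wrappers (`soflr_fit`, `call_activation`, ...), and a `soflr`
command-line tool covers the file-based workflow.

## Worked example

The six-isolate cadmium-induced mean overlap curve is
`1673, 850, 574, 433, 346, 285` for k = 1..6:

```sh
printf 'k,y\n1,1673\n2,850\n3,574\n4,433\n5,346\n6,285\n' > cd_induced.csv
soflr fit cd_induced.csv
```

prints (abridged):

```
d_hat     = 234
T_hat     = 2472.16
p_hat     = 0.52806
adj_r2    = 0.9930
n_required = 15
ci        = [234.079, 234.371]
```

Read: the overlap decay is consistent with ≈234 driver genes plus ≈2472
passenger genes each active with probability ≈0.53 per isolate; the fit
explains 99.3% of the log-scale variance; with 15 independent isolates
the 95% mean-response interval for the common-gene count already sits
within half a gene of `d̂`. (On this printed, rounded curve the adjusted-R²
profile is extremely flat near its peak — the values at d = 233 and 234
differ by less than 1e-6 — so the selected integer is sensitive to
rounding of the input means.)

Is the observed 6-way overlap of 285 probes more than chance? Randomize
the six activated sets (sizes 1189...2389) over the 25,074-probe
universe:

```sh
soflr nulltest --universe 25074 --sizes 1189,1325,1408,1499,1637,2389 \
      --observed 285 --reps 1000000 --seed 1
```

```
exceed_count   = 0
max_simulated  = 2
mean_simulated = 0.001244
p_estimate     = 9.999990e-07     # add-one estimator
p_upper_bound  = 1e-06            # < 1/reps
```

A million random draws never intersect in more than 2 probes (expected
overlap ≈ 0.0013), so 285 shared probes is overwhelmingly non-random.

How many isolates until the passenger overlap dies out on its own?

```sh
soflr passenger-sim --T 5000 --p 0.1,0.3,0.5 --replicates 10 --seed 0
```

```
seed,T,p,mean,se
0,5000,0.1,4.6,0.163
0,5000,0.3,7.7,0.335
0,5000,0.5,14.4,0.427
```

The per-isolate activation probability *p* matters far more than the
passenger-set size *T*.

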