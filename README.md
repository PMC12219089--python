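# recurph

Topological feature extraction from univariate time series, built for
classifying and characterising physiological and dynamical signals
(EMG, ECG, chaotic oscillators) where the *shape* of the reconstructed
attractor carries the diagnostic information.

## The method

For a series `x_1, ..., x_T` the pipeline runs four stages:

1. **Delay embedding** — build state vectors
   `X_i = (x_i, x_{i+τ}, ..., x_{i+(k−1)τ})`, default `k = 3`, `τ = 1`.
2. **Recurrence plot** — the matrix of pairwise Euclidean distances
   `D_ij = d(X_i, X_j)`, viewed as a grayscale image.
3. **0-dimensional persistent homology** — sublevel filtration
   `S(r) = {(i, j) : D_ij ≤ r}` with edge-sharing (V-construction)
   adjacency. Connected components appear at local minima of `D`
   (*birth* `b`) and are absorbed into older components at saddles
   (*death* `d`, elder rule), giving a persistence diagram: the
   multiset `{(b_i, d_i)}` plus one essential class per connected
   component of the full image. The algorithm is a union-find sweep in
   ascending pixel order; a flood-fill Betti-0 counter ships alongside
   it as an independent oracle.
4. **Vectorisation and reduction** — the diagram is rasterised into a
   persistence image

   `PI(b, d) = w(b, d) · Σ_i g(b_i − b, d_i − d)`

   with a Gaussian kernel `g` (bandwidth σ) and squared-lifetime
   weight `w(b, d) = (d − b)²`, on one grid shared by the whole
   cohort; the resulting non-negative feature matrix `V (N × D)` is
   factored by NMF, `V ≈ PQ` (Frobenius objective, multiplicative
   updates), so each sample is summarised by a handful of
   interpretable scores `P_i` against basis images `Q`.

A single NMF score often suffices to separate dynamical classes —
chaotic vs periodic regimes of Chua's oscillator, or signal classes in
labelled cohorts — and the basis images say *which* diagram regions
drive the separation.

## Worked example

```python
from recurph import RecurrencePH, make_labeled_cohort

cohort = make_labeled_cohort({"sine": 20, "logistic": 20}, length=200, seed=0)
res = RecurrencePH(cohort, rank=2, seed=0).fit()
print(res.summary())
print(res.evaluate("logistic", component=0)["accuracy"])
```

prints

```
Recurrence-plot persistent homology / NMF results
====================================================
samples: 40 (train 40, test 0)
embedding: k=3, tau=1
PI grid: 64x64, sigma=0.1187, weight=squared_lifetime/grid
birth/death range: [-0.3562, 2.731]
NMF: rank=2, iterations=2000, final ||V-PQ||=43157.3

component   Q row-norm   mean score   max score
NMF1               6977        7.527       22.52
NMF2               4239        3.176       13.74

mean finite pairs per diagram: 5627.4
1.0
```

The cohort mixes noisy tones with chaotic logistic-map series; a
single NMF component separates the two classes perfectly (best
threshold accuracy `1.0`), because periodic recurrence plots produce a
few long-lived components while chaotic plots produce clouds of
short-lived ones.

The same objects drive the bifurcation experiment: `beta_sweep()`
simulates Chua's oscillator across β ∈ [30, 32], fits one rank-4 NMF
over the whole sweep, and `regime_segments()` reads off the contiguous
β-stretches dominated by each basis component — the periodic windows
and chaotic bands of the circuit.

Every stage is also available as a CLI verb:

```sh
recurph simulate --system chua --beta 30.0 --n 1000 --out series.tsv
recurph embed series.tsv --k 3 --out d.tsv
recurph ph d.tsv --out pd.csv
recurph pi pd.csv --out features.tsv
recurph nmf features.tsv --rank 2 --out model/
recurph pipeline --synthetic sine=20,logistic=20 --rank 2 --out run/
recurph sweep --beta-min 30 --beta-max 32 --step 0.1 --out sweep/
```

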