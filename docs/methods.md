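# Methods

This note records the models, algorithms, parameter choices and
numerical conventions implemented in `recurph`, and what the shipped
tests do and do not establish.

## Recurrence plots from delay embeddings

A univariate series `x_1, ..., x_T` is embedded as
`X_i = (x_i, x_{i+τ}, ..., x_{i+(k−1)τ})`, `i = 1, ..., T − (k−1)τ`.
Defaults are `k = 3` and `τ = 1` (consecutive samples); both are
parameters of every entry point. There is no universally accepted rule
for choosing `k`, and `k = 3` is a common working choice for scalar
signals; mutual-information or false-nearest-neighbour selection of
`(k, τ)` is deliberately out of scope. The recurrence plot is the full
Euclidean distance matrix of the embedded states — no thresholding, no
Theiler window. Distances are computed with `scipy.spatial.distance.pdist`,
which guarantees exact symmetry and a zero diagonal. Because Euclidean
distance is translation invariant, adding a constant to a series leaves
its recurrence plot unchanged (tested).

Multivariate series are not supported in the core: there is no
canonical distance between multichannel states. The persistence stage
accepts any precomputed square matrix, so users can supply their own.

## 0-dimensional sublevel persistence (V-construction)

The distance matrix is treated as a grayscale image filtered by value:
`S(r) = {(i, j) : D_ij ≤ r}`. Adjacency is edge-sharing only
(4-neighbourhood, "V-construction"); diagonal contact does not
connect. Only connected components (H0) are tracked — loops and higher
homology are out of scope.

Algorithm: pixels are sorted by `(value, row-major index)` and
activated in order; each activation unions the new pixel with its
already-active 4-neighbours. A component's birth is the value of its
first (minimal) pixel. When two components merge at value `v`, the one
with the larger birth dies, contributing the pair `(birth, v)` (elder
rule); a birth tie is broken in favour of the earlier-activated root,
which makes the recorded birth *locations* deterministic (the pair
multiset itself is invariant to the tie rule). Components that never
merge are reported as essential classes — exactly one for a connected
image. Zero-persistence pairs (merges among equal-valued pixels) are
discarded by default: they carry zero weight downstream; a flag
retains them.

Correctness is anchored to an independent oracle shipped with the
package: a flood-fill component counter (`scipy.ndimage.label` with
the 4-neighbour structuring element). For random matrices the
diagram-implied Betti-0 curve must equal the flood-fill count at every
realized threshold, exactly; this is the module's central test.

Stability: an ε-bounded perturbation of the image moves each matched
birth and death by at most ε, so the count of features with
persistence > 2ε is preserved. The shipped test verifies this on
integer-valued random matrices with ε = 0.1, where the value gaps make
the count comparison exact; for continuous-valued matrices a feature
whose persistence sits within 2ε of the cutoff can legitimately cross
it, so the count form of the property is only guaranteed with a margin
between the persistence spectrum and the threshold.

## Persistence images

Finite pairs are rasterised on a uniform (birth, death) grid:

    PI(b, d) = w(b, d) · Σ_i g(b_i − b, d_i − d)

with `g` the isotropic bivariate Gaussian density
`exp(−(x² + y²) / 2σ²) / (2πσ²)`. The weight is the squared lifetime
`(d − b)²`, evaluated **at the grid location** and clamped to zero
below the diagonal — the formula above taken literally. The standard
persistence-image literature instead weights each diagram point by its
own lifetime; `weight_mode="point"` provides that variant for
comparison. The two differ measurably (tested) but share the
qualitative effect of suppressing near-diagonal noise, which is the
role the stability theorem assigns to the weight.

On normalisation: a Gaussian kernel written with the 1-D prefactor
`1/√(2πσ²)` but a 2-D exponent is dimensionally inconsistent; this
implementation uses the proper 2-D product density `1/(2πσ²)`, so a
single unweighted point fully inside the grid integrates to unit mass
(tested to 1%). The choice only rescales every feature vector by a
constant and is therefore immaterial to NMF scores up to scale.

Grid defaults: bounds `[0 − 3σ, max death + 3σ]` on both axes computed
over the *whole cohort* (all samples must share one feature space for
NMF), resolution 64×64, `σ = 0.05 × (max death − min birth)`. All are
configurable and are written into a metadata sidecar next to every
feature matrix, so vectors from different runs are comparable only
when their sidecars agree. Essential classes are excluded from the
image by default (their squared lifetime is undefined); a
`cap_essential` option substitutes the maximum pixel value for their
death instead.

## Non-negative matrix factorization

`V ≈ PQ` with `P ≥ 0 (N × D′)`, `Q ≥ 0 (D′ × D)`, minimising the
Frobenius norm by classical multiplicative updates, which keep the
factors non-negative and never increase the objective (asserted on
every fit in the tests, with 1e-10 slack for float noise). A small
`1e-12` floor in the update denominators prevents division by zero.

Initialisation draws both factors from `uniform(0, 1)` scaled by
`sqrt(mean(V)/rank)`, from a seeded generator, so the initial product
has the magnitude of `V`; fits are bitwise reproducible given the
seed. Convergence defaults: `max_iter = 2000`, relative-improvement
tolerance `1e-6`. Because NMF components have no intrinsic order, the
returned components are sorted by descending Euclidean row-norm of
`Q`; "NMF1" is always the dominant basis. The factorization is scale
indeterminate (`P diag(s) · diag(1/s) Q = PQ`); tests pin this down
explicitly rather than pretending uniqueness.

New samples are scored against a fixed basis by the multiplicative
update restricted to `P` — the train/transfer protocol: fit the basis
on training rows only, transform held-out rows, evaluate there.

Rank is expert-chosen per experiment (4 for the Chua sweep, 2 for
labelled cohorts by default); cophenetic/AIC/Bayesian rank selection
is out of scope. Feature vectors are not normalised before NMF by
default.

## Synthetic generators

**Chua's oscillator** in the classic dimensionless form

    dx/dt = α (y − x − h(x)),   dy/dt = x − y + z,   dz/dt = −β y,
    h(x) = m₁x + ½(m₀ − m₁)(|x + 1| − |x − 1|)

with α = 15.6, m₀ = −8/7, m₁ = −5/7 and β swept over [30, 32]. Across
this window the circuit passes through periodic windows and chaotic
bands (verified here by the autocorrelation criterion below: periodic
at β = 30.0 and 30.4, chaotic at 30.2, 31.0, 31.8). Integration is
fixed-step RK4 with `dt = 0.01`; retained samples are x(t) at unit
time spacing (`sample_interval = 1.0`) after a 500-time-unit
transient, from initial state `(0.1, 0, 0)`. `dt` was fixed by a
step-halving check: over a short horizon (before exponential error
growth dominates) halving `dt` changes retained samples by < 1e-4
relative. Divergence (|state| > 1e6) raises an explicit error naming
`dt`. In the large-β chaotic band the system has two coexisting
attractors with separate basins; only the default initial state's
basin is explored.

Regime labels in tests use an autocorrelation criterion — periodic
means some lag has autocorrelation > 0.95 — rather than Lyapunov
exponents, to keep the test surface simple and deterministic.

**Logistic map** `x ← r·x(1 − x)` (chaotic at r = 4), **noisy tones**
(unit amplitude, random phase, Gaussian noise sd 0.05, period 20
samples) and **white noise** make up the labelled cohorts. Defaults
(20 + 20 samples, length 200) give a cohort where one NMF component
separates tones from chaos perfectly at the shipped seed.

What the synthetic cohorts emulate — and what they do not: they
reproduce the *topological* contrast between periodic and aperiodic
recurrence structure that the method targets, but they have none of
the artefacts of physiological recordings (baseline wander, sensor
noise correlated in time, class imbalance, inter-subject variability).
Passing the synthetic end-to-end tests shows the pipeline wiring and
the separability mechanism work; it does not certify clinical
performance. Readers for UCR/UEA-style label-first tables are included
so real cohorts can be analysed with the same objects, but no data
download is performed or required.

## Pipeline and sweep conventions

One persistence-image grid is computed per cohort (from training rows
when a split is given) and shared by all samples; this is asserted,
not assumed. The β-sweep fits **one** NMF across all β so that scores
are comparable along the axis; per-β fits would make the component
labels arbitrary at every grid point. Regime segmentation reads the
dominant (argmax) component per β and reports contiguous stretches;
with the shipped defaults (step 0.1, series length 500, rank 4) the
detected change points bracket the known transitions near β ≈ 30.3,
30.45 and 31.1. Desk-scale sizes (length 500, 21 grid points) were
chosen so the full sweep completes in about two minutes on one CPU
while preserving the regime structure; longer series sharpen the
segmentation but change nothing qualitative.

Every fitted result can be written to a directory containing the
feature matrix with its grid sidecar, both factors, scores, the exact
configuration and the sample manifest — enough to re-run
bit-identically.

## Known limitations

- Only H0 under the V-construction; no loops, no 8-neighbour
  adjacency, no superlevel or erosion-distance filtrations.
- The persistence stage is O(M² α(M²)) in the number of embedded
  states M per series (union-find over M² pixels); series much beyond
  10⁴ samples become expensive.
- The union-find sweep is pure Python; it is the pipeline's bottleneck
  (~1 s per 500-point series).
- Frequency information is invisible by construction: two orbits with
  the same shape but different (or drifting) speeds give identical
  recurrence geometry.
- NMF is a non-convex fit; different seeds can find different local
  minima. Component identity across runs is stabilised only by the
  row-norm ordering, not guaranteed.
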