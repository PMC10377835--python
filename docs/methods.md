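# Methods

This note documents the models and procedures implemented in `oraldx`,
the parameters that matter, the numerical conventions chosen where the
design was genuinely open, and the limits of what the synthetic studies
demonstrate.

## Preprocessing

**Median filter.** A square sliding window (default 7×7) replaces each
pixel by the neighbourhood median.  The border is padded by edge
replication of radius `(window−1)/2`; zero padding would darken the rim of
bright lesions.  The filter is implemented by `scipy.ndimage.median_filter`
with `mode="nearest"`, which is exactly this convention.

**CLAHE.** The image is resized to `M×M` (default 256, bilinear) so the
`m×m` tile grid (default m = 32, i.e. 8×8 tiles) is exact.  Per tile, the
histogram over `Ngray = 256` levels is clipped at `CL = Ncl·Navg` with
`Navg = m²/Ngray` and normalized clip limit `Ncl = 0.002`; the clipped
mass is redistributed uniformly (integer remainder handed out one count
per bin from bin 0 upward, so the pixel count is conserved exactly), and
the tile mapping is the CDF of the clipped histogram scaled to
`[0, Ngray−1]`.  Pixels are remapped by bilinear interpolation between the
four surrounding tile mappings; beyond the outermost tile centres the
nearest mapping is replicated.  Redistribution is single-pass — there is
no iterative re-clipping.

A practical note on the default: with `Ncl = 0.002` the count threshold is
below one count per bin, so after clipping and uniform redistribution each
tile histogram is essentially flat and the mapping is close to the
identity — the default configuration is a deliberately conservative
enhancer.  Larger `Ncl` (0.01–0.05) produces conventional CLAHE behaviour;
the implementation covers the whole range.

## Rough-set K-means segmentation

Each non-overlapping 4×4 window is quantized to 8 uniform gray bins
(over the full 0–255 range, so windows are comparable) and described by
five run-length statistics computed from horizontal runs: short-run
emphasis, long-run emphasis, gray-level non-uniformity, run-length
non-uniformity and run percentage.  Smooth regions produce few, long runs;
textured regions many short ones — this contrast, not mean intensity, is
what separates lesion from background.

Clustering follows the rough K-means scheme: with centers `c_1..c_k`, a
vector joins the lower and upper approximation of its nearest cluster
unless some other center is within `threshold` of the nearest distance
(difference form `d_j − d_i ≤ threshold`), in which case it joins only
the upper approximations of all such clusters.  Centers update as
`w_lower · mean(lower) + (1−w_lower) · mean(boundary)`; with an empty
boundary the plain lower mean, with an empty lower set the plain boundary
mean.  Defaults: `k = 2`, `w_lower = 0.7`, `threshold` = 0.1 × the mean
nearest-center distance of the first assignment pass (scale-free), at most
100 iterations, convergence when the largest center displacement is below
1e−6.  Ties in the nearest center go to the lowest cluster index.

Degenerate-state handling: when all items fall into the boundary of every
cluster (which happens whenever centers coincide — e.g. both initial
draws land in the dense background mode) the weighted means merge the
centers permanently.  A center that coincides with an earlier one is
therefore re-seeded from a random feature vector, the same remedy used for
an empty cluster.  Feature vectors are z-scored before clustering inside
`segment_image` so no single statistic dominates the Euclidean metric.

The lesion cluster is the one whose member windows have the higher mean
quantized-intensity variance; window labels (boundary-only windows take
the nearest-center label) are painted back at 4×4 resolution.

## Feature extraction

The GLCM is computed at offset (0, 1) with 16 uniform levels, restricted
to pixel pairs entirely inside the mask, symmetrized and normalized.
Texture statistics use the standard Haralick definitions: contrast
`Σ(i−j)²p`, energy `Σp²`, entropy `−Σp ln p`, homogeneity `Σp/(1+|i−j|)`,
correlation as the Pearson correlation of co-occurring level pairs
(defined as 0 for a constant region).  Intensity mean/variance/standard
deviation are computed over masked pixels.

Geometric descriptors use the largest 8-connected foreground component.
Two conventions required a decision:

* **Perimeter** uses the Crofton estimator with 4 directions
  (`skimage.measure.perimeter_crofton`).  A plain 8-connected boundary
  chain with weights (1, √2) overestimates a smooth contour by ~5.5% on
  average, which biases the irregularity index `4π·Area/P²` of a digital
  disk down to ~0.90; the Crofton estimate is close to unbiased for
  smooth contours (disk of radius 20 → 0.97).
* **Axis lengths** `a ≥ b` are "equivalent rectangle" lengths:
  `√(12·λ)` of the eigenvalues of the pixel-coordinate covariance with a
  +1/12 continuous-pixel correction per coordinate.  Under this scaling a
  solid w×h rectangle yields exactly `a = max(w,h)`, `b = min(w,h)` (so
  rectangularity `Area/(a·b)` is 1 for rectangles), and a single pixel
  yields `a = b = 1`, avoiding zero-division for thin regions.

The composite indices are implemented as defined in the feature table
this package mirrors, including two unconventional ones kept verbatim:
form factor `Area/a²` and elongation `2√(Area/(aπ))`; eccentricity is
`2√(a²−b²)/a` (0 for a disk, and may exceed 1 for elongated shapes).
Hu moments φ1–φ3 use the standard normalized central moments with the
minus-sign form of φ3.

## The competitive search optimizer

Minimization over a box, population `n`.  Each round the population is
ranked (stable ties by index) and split into the excellent group (top
`EC`) and the general group.  With per-contestant learning ability
`A ∈ [0,1]`, resampled uniformly every iteration:

* excellent, `A > L1`: `Y ← Y + A·S1·ρ·(ub−lb)`, `S1 ∈ [LB, UB]/100`,
  `ρ ∈ {−1,0,1}`;
* excellent, `A ≤ L1`: same with `S2 ∈ [0, LB]/100`;
* general, `A > L1`: `Y ← Y + α·Q` (same scalar on every coordinate,
  `α ∈ [−1,1]`, `Q ∈ [0,2]`);
* general, `A ≤ L1`: `Y ← Y ⊙ L2·F·A` with `L2 ∈ {±1}^d`, `F = P·o`,
  `P ~ N(0,1)`, `o ∈ {0.1,…,0.5}` — a *replacement*, not a perturbation,
  implemented as printed in the source formulation;
* all contestants with `A > L3` then move toward the global best:
  `Y ← Y + (Gbest − Y)·A`;
* the `RC` worst contestants (never the current best) are replaced by
  fresh uniform random ones.

The amendment (ACSO) adds: a sine–cosine update of the round's single
worst contestant, `Y ← Y + a1·{sin,cos}(a2)·|a3·Gbest − Y|` with `a1`
decaying linearly from γ to 0 (branching on `a4 < 0.5`), and
opposition-based learning — with probability `JR` the reflection
`lb + ub − x` is evaluated and kept if better.

Positions are clamped to the box after every operator; non-finite
objective values are logged and treated as +∞; the global best is elitist,
so the cost history is non-increasing; objective evaluations are counted
exactly.  Defaults for constants the source formulation leaves open:
`L1 = 0.5`, `L3 = 0.7`, `EC = n/2`, `RC = max(1, n/10)`, `UB = 20`,
`LB = 5` (percent), `γ = 2`, `JR = 0.3`.

**Observed behaviour.** The multiplicative general-group operator makes
the optimizer an aggressive exploiter: on the four 30-D validation
benchmarks (population 60, 250 iterations) it reaches ~1e−9 on Sphere and
Rastrigin, ~1e−5 on Ackley and ~3e−2 on Rosenbrock — several orders below
the published protocol's reference averages on Sphere/Rastrigin and
within one order of magnitude on Ackley/Rosenbrock.  Because the plain
CSO already converges to numerical zero on these unimodal-and-regular
benchmarks, the amendment is cost-neutral there: ACSO and CSO final costs
differ only at seed-noise level (~1e−10), and a one-sided median
comparison between them is effectively a coin flip.  This is recorded as
a known limitation rather than tuned away.

## Feature selection and SVM tuning

The wrapper cost is `C = w1·(1−ACC) + w2·(Σ_selected F / Σ_all F)` with
`w1 = 0.6`, `w2 = 0.4`.  ACC is the stratified k-fold (default 5)
cross-validated accuracy of a *fixed* default RBF SVM (standardized
inputs, C = 1, γ = scale) so the wrapper objective stays cheap and
well-defined; the per-feature F-score is
`[(m⁺−m)² + (m⁻−m)²] / [s⁺² + s⁻²]` with unbiased class variances floored
at 1e−12 (perfectly separated features score large but finite).  Subsets
are encoded on the continuous unit box and decoded at 0.5; an empty decode
is repaired to the single highest-coordinate feature.  Costs are cached
per decoded mask.  Note that the second term *charges* for selected
F-score mass: the cost trades accuracy against retained discriminative
mass, and its optima are very sparse subsets (often a single strong
feature).  A multi-group F-score variant is exposed as a descriptive
statistic only.

SVM tuning searches `log10 C ∈ [−2, 3]`, `log10 γ ∈ [−4, 1]`, minimizing
the mean over stratified folds of the half-sum-of-squares label error
`½Σ(z*−z)²` (each misclassified ±1 label contributes 2).  Standardization
statistics are computed on training folds only.  The default
hyperparameter point is injected into the initial population, so tuning
can never end worse than the default on the tuning objective.  Decision
values of 0 map to label +1.

## Evaluation and pipeline

Precision and recall are macro-averaged one-vs-rest over the classes in
the report; accuracy pools the per-class tables; F1 is the harmonic mean
of the macro pair; division-by-zero terms are 0.  The pipeline splits
70/30 stratified, runs selection and tuning on the training rows only,
and evaluates on the held-out rows.  Every stage seed derives from one
master seed, so runs are byte-reproducible; per-image failures are logged
and skipped.

## Synthetic data

The image generator emulates two-class lesion photographs: a textured
background (smooth Gaussian field, amplitude 6 gray levels) with an
embedded ellipse whose *texture* differs by class — cancer-like: amplitude
55, correlation scale 2.5 px, irregular (harmonically perturbed) boundary;
benign-like: amplitude 25, scale 4 px, smooth boundary — plus 2% impulse
noise and Gaussian noise (σ = 3).  Texture scales are chosen to survive
the 7×7 median filter.  Lesion and background mean levels differ by only
25 gray levels, so a trivial intensity threshold is a poor segmenter and
the run-length features must carry the separation.  The table generator
emits class-conditional Gaussian columns with a stated mean separation for
a known informative subset and shared-distribution noise columns, with
shuffled column order.

What passing the synthetic studies does **not** show: real lesion
photographs have colour cues, specular highlights, non-elliptical and
poorly delimited lesions, and inter-patient appearance variation none of
which the generator models; perfect held-out accuracy on the synthetic
study is a property of the clean class design, not a clinical claim.

## Problem sizes used in the shipped studies

Benchmark validation: 4 functions × 35 runs, d = 30, population 60, 250
iterations.  End-to-end study: 80 images (40 per class) at 256×256,
selection with population 30 × 60 iterations, tuning with population
20 × 30 iterations, 5 folds.  Parameter-recovery study: 10 seeds of the
3-informative / 7-noise table with 40 samples per class.  These sizes keep
the full test suite and the reproduction script in the minutes range on a
single CPU.

## Known limitations

* The selection cost's F-score term penalizes retained discriminative
  mass (see above); with strongly informative features its optimum is a
  near-singleton subset.  This is faithful to the formulation the package
  mirrors, but users wanting high recall of all informative features
  should treat `w2` as a dial or use the accuracy term alone.
* The amendment's sine–cosine/opposition operators show no measurable
  benefit over the plain CSO on the four classic benchmarks because the
  base algorithm's multiplicative operator already prevents premature
  convergence there.
* CLAHE at the default normalized clip limit is nearly an identity
  mapping (by design of the printed constant); raise `Ncl` for visible
  enhancement.
* Rough K-means is a local method: results depend on the seeded
  initialization, and the duplicate-center re-seed makes degenerate
  collapses recoverable but adds iterations on hard instances.
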