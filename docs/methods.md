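# Methods

## Self-organizing map

### Model and training procedure

The map is a planar W × H grid of units, each with a tuning vector in the
input feature space R^f. Training proceeds in epochs t = 0..T−1; every epoch
presents the full input set (reshuffled per epoch) in batches. For each
batch, best-matching units (BMUs) are assigned by minimum Euclidean distance
against the codebook state at the start of the batch; the per-image updates

    t_{(w,h)} ← t_{(w,h)} + L_t · exp(−D²_{(w,h),BMU} / 2σ_t²) · (x − t_{(w,h)})

are then applied sequentially in batch order. Freezing BMU assignment at the
batch boundary makes the within-batch assignment independent of update
order, while the sequential tuning updates keep the classic online-SOM
character; with the decaying schedules the two interpretations converge, but
the frozen-assignment variant is what this package implements and what its
determinism contract covers. All units are updated on every step — the
Gaussian neighborhood decays smoothly with no radius cutoff. D is Euclidean
distance on grid coordinates (0-based (row, col)); BMU ties break to the
smallest row-major index, which makes every result reproducible bit-for-bit
from the config seed.

Both schedules are linear: L_t = L₀(1 − t/T) and σ_t = σ₀(1 − t/T), constant
within an epoch. An exponential radius schedule
σ_t = σ₀·exp(−(t/T)·ln(σ₀/ε)) is available behind
`TrainConfig.radius_schedule` for comparison. The radius is floored at
ε = 1e−6 so the neighborhood never degenerates to division by zero in the
final epochs.

### Initialization

The top two eigenpairs of the covariance of a mean-centered random subsample
(default 400 rows, drawn without replacement from the config seed) define a
principal plane. The grid aspect W/H is chosen among factor pairs whose
product is closest to the requested unit count, minimizing
|log(W/H) − log(√λ₁/√λ₂)| — the aspect lives on the √eigenvalue scale
because that is how the axes are stretched. Unit (w, h) starts at

    mean + a_w·√λ₁·v₁ + b_h·√λ₂·v₂,   a_w, b_h linearly spaced over [−1, 1].

The span [−1, 1] (one standard deviation along each principal axis) is a
design choice; the training phase quickly adapts the map's extent, and the
choice only needs to center the sheet on the data manifold with the right
orientation. `TrainConfig.grid_shape` can bypass the aspect heuristic when a
specific grid is wanted.

### Diagnostics

The quantization error (mean distance of each input to its BMU tuning) is
recorded at initialization and after every epoch. `similarity_by_distance`
bins the Pearson correlations of unit tuning vectors by grid distance
(rounded to integer bins, self-pairs excluded, zero-variance units excluded
with an exclusion count) — on a well-ordered map this curve decreases
monotonically.

## Map statistics

Activations are raw per-unit dot products t·x with no centering or norm
correction; everything downstream is built from per-image activations.
Condition moments use the unbiased (n−1) variance and require at least two
images per condition. Preference maps take the condition with the highest
mean activation per unit; strength is the absolute margin over the
runner-up (for two conditions, the absolute difference of the two means);
exact ties resolve to the earlier condition in the list and are flagged.

d′ divides the target-vs-rest mean difference by the pooled standard
deviation √((σ²_t + σ²_r)/2); SI divides by the sum of means and is bounded
in [−1, 1] for nonnegative activations. Units with a vanishing denominator
are marked undefined (NaN plus a mask) rather than coerced to zero, and
downstream statistics refuse undefined inputs explicitly. A non-target
exclusion list supports contrasts like "bodies vs everything except faces".

The nonuniformity score softmax-normalizes a selectivity map (temperature 1,
natural log) into a distribution P over units and returns
√(KL(P‖Q)/2 + KL(Q‖P)/2) against the uniform Q. This symmetrized-KL form is
the package's primary statistic; it is zero iff the map is flat, invariant
to adding a constant to all scores, and unbounded as a single unit comes to
dominate. The textbook Jensen–Shannon distance (KL against the mixture
M = (P+Q)/2, bounded by √ln2) is available via `jensen_shannon=True`.

## Overlap inference

`roc_overlap` sorts units by selectivity (descending, row-major tie-break)
and, for thresholds k = ceil(pct·n/100), pct = 1..100, computes the
proportion of all zone-a- and zone-b-preferring units inside the top-k set.
The curve is (zone-b fill on x, zone-a fill on y) with (0,0) prepended, and
the AUC is its trapezoidal area: 0.5 is chance, 1.0 means the selective
units exhaust zone a before touching zone b. AUC > 0.5 therefore reads
"selective units concentrate in zone a". The area between the curve and the
diagonal is exposed as `auc_above_diagonal = auc − 0.5`. By construction
AUC(a,b) + AUC(b,a) = 1 and the AUC is invariant under any strictly
monotone transform of the scores.

`permutation_test` shuffles the selectivity scores across units (preference
map fixed) and recomputes the AUC, 1000 times by default. The p-value is the
plain proportion of null AUCs strictly greater than the observed one; an
add-one smoothed variant (b+1)/(n+1) is available for calibration-sensitive
uses (the plain proportion can return exactly 0). Calibration under the
null (selectivity independent of the map) puts the rejection rate at
α = 0.05 near nominal (~0.05 across 500 replicates in the acceptance run).

Moran's I with binary rook (or queen) adjacency measures large-scale
spatial clustering of a preference map. A caveat from the randomization
variance of I: on a lattice with S₀ = twice the edge count,
sd(I) ≈ √(2/S₀) ≈ 0.036 for ~400 units, so individual label shuffles
scatter well beyond ±0.05 even under a perfect null; null comparisons on
maps of this size should use the empirical shuffle quantiles (the observed
maps here score I ≈ 0.8–0.9 against a null 95th percentile of ≈ 0.07), not
a fixed small cutoff.

`rdm` (1 − Pearson between sample feature vectors, exactly symmetric with a
zero diagonal) and `mds_embed` (scikit-learn SMACOF metric MDS on the
precomputed dissimilarities, seeded, returning coordinates and raw stress)
summarize the representational geometry of the input space itself.

## Synthetic object space

The generator emulates the statistical shape this analysis assumes of a
rectified deep-net embedding over an animacy × real-world-size stimulus
design:

* two random orthonormal factor axes u_anim, u_size in R^F (random rather
  than axis-aligned, so nothing downstream can pass by coordinate accident);
* category centroids at baseline + (±g_a)·u_anim + (±g_s)·u_size + isotropic
  offset;
* images = centroid + isotropic noise, clipped at zero (after noise, which
  shifts means slightly — accepted as the analogue of rectification);
* two focal categories ("faces" in the animate/small cell, "scenes" in the
  inanimate/big cell) with much tighter centroid offsets, giving the nested
  mesoscale clusters the overlap analysis looks for.

Defaults: F = 256, 16 categories × 60 images = 960 samples balanced over the
four cells, baseline 3.0, gains g_a = 4.0 and g_s = 3.5, category spread
1.0, image noise 0.5, focal tightness 0.25. The dimensionality is kept at
256 (a real penultimate layer is an order of magnitude wider) for desk-scale
runtime; it is a config knob. The gains are set so each factor's two sides
are separated by ≈ 3–3.6 within-cluster standard deviations along its axis —
strong enough that sign projections recover the design >99% of the time,
weak enough that images of different categories still overlap heavily, as
real embeddings do.

What the generator does **not** emulate: the heavy-tailed, sparse activation
statistics of real rectified embeddings; dozens of object categories with
graded (non-binary) animacy and size; correlated (non-isotropic) noise; any
image-level structure (there are no images). Passing tests therefore
demonstrate that the pipeline recovers planted manifold structure correctly
and reproducibly — not that any particular real network organizes this way.

`generate_planar_manifold` is the second fixture: points uniform on a 2D
rectangle (aspect 2:1) embedded by a random orthonormal pair with tiny
off-plane jitter (sd = 1e−3 × extent). A SOM trained on it must recover the
2D ordering, measured as the Spearman correlation between pairwise grid
distances and pairwise tuning distances over all unit pairs (≈ 0.87 at the
acceptance run's sizes: 1000 points, 64-D, 10 × 10 grid, 30 epochs).

## Problem sizes and numerical choices

The shipped analyses run at: 960 × 256 object space, 100-epoch training on
the default (~400-unit) grid and a fixed 12 × 12 grid; 1000 × 64 planar
manifold with a 10 × 10 grid and 30 epochs; 1000-permutation nulls; 500
calibration replicates. The full acceptance run takes about a minute on one
CPU. Oracle-equivalence tests use exact tolerances (1e−10; BMU identity
exact); stochastic assertions use wide, pre-stated margins (e.g. Spearman
> 0.5, AUC > 0.8) rather than tuned ones.

Degenerate inputs are rejected loudly rather than patched: zero-variance
init samples, singleton conditions (named in the error), constant feature
vectors in the RDM (sample named), empty preference zones, undefined
selectivity entering ROC or nonuniformity computations. Codebook archives
are a raw `.npy` tensor plus a JSON sidecar so that a fixed seed yields
byte-identical files (zip-based containers embed timestamps and would not).

## Known limitations

* The batch-update order-dependence noted above is resolved by convention;
  other conventions converge statistically but not bit-wise.
* Linear schedules reach (near-)zero at t = T−1 by design; maps are
  effectively frozen over the last epochs, so very small T with large σ₀
  underfits.
* The planar grid has edges (no toroidal topology); border units compress
  their catchment, visible as mild edge effects in preference maps.
* `mds_embed` inherits SMACOF's local minima; the default 8 restarts are
  adequate at these sizes but coordinates are only defined up to rotation,
  reflection, and restart luck.
* Moran's I null behavior on small grids (see above) limits fixed-threshold
  null criteria; use shuffle quantiles.
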