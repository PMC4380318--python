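# Methods

## Elliptic Fourier delineation

A grain contour is an ordered closed loop of boundary pixels. Traversing it
at constant speed makes both coordinates periodic in the arc-length
parameter t, and the Fourier coefficients (an, bn) of x and (cn, dn) of y
are computed with the piecewise-linear closed forms (the Kuhl–Giardina
construction): the polygon through the points is integrated exactly, so the
result does not depend on point spacing. Arc length uses Euclidean segment
lengths, not unit pixel steps. The offsets a0 and c0 locate the contour in
the image and carry no shape information; they are computed but excluded
from every downstream vector.

Boundary extraction from binary masks uses Moore-neighbor tracing of the
largest connected component (8-connectivity), returning the ordered loop of
boundary pixel centres. All traced contours are canonicalized to
counterclockwise so the coefficient handedness is fixed.

### Standardization

The raw coefficients vary with contour size, rotation and the arbitrary
starting pixel. Standardization removes all three using the first-harmonic
ellipse: (i) the trace phase is shifted so the parameterization starts at
an end of the major axis (theta from the first-harmonic cross terms),
(ii) the plane is rotated so the major axis lies along x, and (iii) all
coefficients are divided by the semi-major axis length. This forces
a1 = 1, b1 = 0, c1 = 0 exactly, leaving a 4N − 3 descriptor
(77 entries at the default N = 20).

The construction admits a joint 180°/half-period ambiguity (both ends of
the major axis are valid starting points). We resolve it deterministically:
of the two candidates, keep the one with the larger a2, breaking exact ties
toward the smaller phase shift. Because the two candidates' a2 values are
exact negatives, this effectively selects a2 > 0; contours with an exact
two-fold symmetry (a2 = 0, e.g. perfect ellipses) sit on the tie and are
resolved by the phase rule. This convention may not bit-match the historical
SHAPE program's internal choice, but it is invariant to similarity
transforms of the input, which is the contract that matters. Reflection
(chirality) is deliberately not normalized — mirrored outlines give
different descriptors — and the sign of d1 records handedness.

### Approximation error E²_N

E²_N is the ratio of summed squared displacements between observed and
truncated-series coordinates (evaluated at each pixel's arc-length
parameter) to the total coordinate variance about the centroid. One
caveat documented here because tests rely on it: the truncated Fourier
series minimizes the *continuous* L² error along the polygon, not the
discrete vertex sum, so on noisy contours E²_N may increase by O(1/P)
relative terms near the noise floor as N grows. On smooth outlines it is
strictly non-increasing; on pixel/noisy data it is monotone to ~1e−3
relative. Similarly, a curve that is a finite Fourier series in its *own*
parameter is generally not one in arc length (only the circle is exactly
constant-speed), so "exact representation" checks use the circle and
low-amplitude harmonic curves.

## Genomic prediction models

Genotypes are coded 1/−1 for the two homozygous classes of inbred
accessions; fractional values in [−1, 1] (mean-imputation scores) are
accepted everywhere and used as-is. A trivial marker-mean imputation hook
fills missing values at load time; model-based imputation is out of scope.

* **RR (GBLUP).** y = μ + g + e with g ~ N(0, σ²g K), K the VanRaden-type
  realized relationship: column-center the scores, divide the cross-product
  by the summed column variances 4p(1−p) (diagonal ≈ 1). The variance ratio
  λ = σ²e/σ²g is estimated by REML in the eigenbasis of K (EMMA-style
  profiling): a 121-point log-spaced grid over [1e−6, 1e6] followed by one
  parabolic refinement, vectorized across all 77 descriptor responses,
  which share the eigendecomposition. Predictions are
  μ̂ + K_cross (K + λ̂I)⁻¹ (y − μ̂). Constant responses short-circuit to the
  mean. Kernels failing the PSD tolerance receive a logged ridge jitter of
  1e−8 · trace/n before fitting errors out.
* **KRR.** Identical machinery with the Gaussian kernel
  exp(−h‖x−x′‖²); h = 2/d²ₘ, with dₘ the median Euclidean distance over
  unordered distinct pairs (self-distances excluded — they are zero and
  would bias the median downward).
* **PLS.** Multi-response PLS2. Each component's X-weight is the dominant
  left singular vector of Xc′Yc — the exact fixed point of the NIPALS power
  loop, computed directly so results carry no iteration-tolerance artifacts
  and are bit-reproducible. Scores are normalized to unit length; X and Y
  are both deflated by t. Predictions use B = W(P′W)⁻¹C′.
* **KPLS.** The kernel analogue with the same deflation scheme: the
  double-centered kernel replaces Xc Xc′, u is the dominant eigenvector of
  Yc Yc′ Kc (via the small symmetric problem Yc′KcYc), and both Kc and Yc
  are deflated by (I − tt′). Test kernel rows are centered with training
  statistics. With a linear kernel K = XX′ the predictions coincide with
  PLS to machine precision — the module's central equivalence check.

### Component selection

The number of PLS/KPLS components (1..30) is chosen inside each training
fold by ten-fold inner cross-validation minimizing the shape-space PRESS
(T/2 times the summed squared descriptor error on held-out accessions).
Ties within 1e−9 relative resolve toward fewer components. The Gaussian
bandwidth, relationship-matrix centering, REML variance ratios and inner
folds are all recomputed from the training split only; nothing leaks from
held-out accessions. Whether variance components should instead be fixed
globally is unknowable from the method description we follow; per-fold
re-estimation is the leakage-free default.

## Accuracy machinery

Because the coordinate functions are Fourier series, the integral over one
period of the squared displacement between two contours collapses to
(T/2) Σn [(Δan)² + (Δbn)² + (Δcn)² + (Δdn)²] — the closed form used for the
per-accession squared shape error (T = 1 throughout; Q² is invariant to T).
PRESS sums these errors; Q² = 1 − PRESS / (T/2 · total among-accession sum
of squares about the grand-mean descriptor). Q² = 1 iff every prediction
equals the accession average, 0 for grand-mean prediction, negative when
worse than that.

Cross-validation: leave-one-out, or ten-fold repeated 10 times. Fold
assignment is a random permutation cut into blocks of near-equal size,
derived deterministically from the user seed, so different methods run on
identical splits and are comparable pairwise. Each ten-fold replication's
Q² pools all of its held-out predictions (rather than averaging per-fold
Q² values); report-level Q²/PRESS are means over replications. Method
pairs are compared with the exact two-sided Wilcoxon signed-rank test on
the 10 replication Q² values; zero differences are dropped before ranking
(logged), and all-zero differences return p = 1.

## Synthetic data generator

The generator emulates a germplasm collection: n accessions (default 200)
with 300 biallelic markers (allele frequencies uniform in [0.1, 0.5],
optional first-order LD), 20 additive QTL, and 4–6 grains per accession.
Grain outlines come from a tapered superellipse with three latent
parameters — log length-to-width ratio (base ln 2.2, the dominant axis, as
in real grain collections), taper (base 0.18; also what breaks the
two-fold symmetry so the standardization tie-break is well separated), and
squareness exponent (base 2.1). Per-parameter scales (0.15, 0.06, 0.10 on
the latent scale) were chosen once to span visually plausible grain shapes.

Heritability h² is the grain-level intraclass correlation: genetic sd
√h²·scale among accessions, within-accession (grain) sd √(1−h²)·scale
(times a configurable noise multiplier). QTL effects are drawn i.i.d.
normal and rescaled so the realized genetic variance hits the target
exactly; h² = 0 therefore yields literally zero among-accession latent
variance, with the residual among-accession descriptor variation coming
only from averaging a finite number of noisy grains. Each grain is
randomly rotated and its trace cyclically re-started before descriptor
extraction, exercising the standardization invariances on every simulated
dataset. Rasterization draws filled polygons at a configurable size; with
no explicit scale the outline is fitted with a 5% margin, with an explicit
scale an outline reaching the border is an error.

What a green test does *not* establish: the generator has no population
structure, no realistic LD maps, no dominance/epistasis, and its outline
family is smoother and more symmetric than real grain photographs, so
absolute Q² levels on real collections will differ; the tests validate the
machinery and its statistical behavior, not any dataset-level accuracy
claim.

## Numerical choices and limitations

* Eigenvalues of kernels are clipped at zero after the PSD check;
  REML grid bounds [1e−6, 1e6] cap the estimable signal-to-noise range.
* PLS rank exhaustion raises; constant Y yields a zero-component model
  predicting the mean.
* The Wilcoxon test needs ≥ 5 pairs; ten-fold with fewer than 11
  accessions reduces the fold count with a warning.
* Descriptor tables must have 4N−3 coefficient columns named
  a2..aN, b2..bN, c2..cN, d1..dN; a column-mapping override adapts
  external exports whose headers differ.
* LOOCV with nested component selection is O(n² folds × inner fits); at
  n = 200 and 300 markers a full four-method comparison takes ~2–3 minutes
  on one CPU.
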