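# grainshape

Genomic prediction of grain *contour shape* — not just length and width —
from genome-wide SNP genotypes, for quantitative geneticists and breeders
working with cereal germplasm collections.

The pipeline quantifies each grain's closed outline with **elliptic Fourier
descriptors (EFDs)**: the boundary, traversed at constant speed over one
period *T*, has coordinate functions

```
x(t) = a0 + Σn [ an cos(2nπt/T) + bn sin(2nπt/T) ]
y(t) = c0 + Σn [ cn cos(2nπt/T) + dn sin(2nπt/T) ]
```

truncated at N = 20 harmonics. After standardizing against size, rotation
and the trace starting point (which forces a1 = 1, b1 = 0, c1 = 0), the
remaining 4N − 3 = 77 coefficients

```
f = (a2..aN, b2..bN, c2..cN, d1..dN)'
```

form the shape phenotype. Four genomic prediction models map marker
genotypes **x** ∈ [−1, 1]^m to **f**:

* **RR** — ridge regression / GBLUP with the realized additive relationship
  matrix, variance ratio by REML (one descriptor at a time);
* **KRR** — the same mixed model with a Gaussian kernel
  κ(x, x′) = exp(−h‖x − x′‖²), bandwidth h = 2/d²ₘ from the median pairwise
  distance;
* **PLS** — multi-response linear partial least squares on all 77
  descriptors jointly;
* **KPLS** — kernel PLS (Rosipal–Trejo deflation), component count chosen
  by nested ten-fold cross-validation (max 30 components).

Predicted descriptor vectors reconstruct directly into 100-point contours.
Accuracy uses the shape-space geometry: the squared prediction error of an
accession is the exact integral of squared displacement between its
predicted and average contours, (T/2) Σn [(ān−ân)² + … + (d̄n−d̂n)²];
summing over accessions gives PRESS and

```
Q² = 1 − PRESS / [ (T/2) Σl Σn (deviations of f̄l from the grand mean)² ]
```

is the cross-validated proportion of shape variation explained (computed
under leave-one-out or 10× repeated ten-fold CV with splits shared across
methods, compared pairwise by the exact Wilcoxon signed-rank test).

A synthetic-data module generates the whole stated world — grain-like
outlines (dominant length-to-width-ratio axis, taper, squareness) with
additive QTL effects at controllable heritability, multiple grains per
accession, and rasterized binary masks — so the full pipeline is testable
without any external data.

## Worked example

```sh
grainshape simulate --n-accessions 60 --n-markers 120 --n-qtl 15 \
    --heritability 0.8 --seed 3 --out-dir demo
grainshape crossval --genotypes demo/genotypes.csv \
    --descriptors demo/descriptors.csv \
    --method RR --method KPLS --scheme loocv --seed 1 --out-dir demo/cv
```

prints

```
RR loocv: Q2 = 0.4849 (demo/cv/RR_loocv_summary.json)
KPLS loocv: Q2 = 0.1664 (demo/cv/KPLS_loocv_summary.json)
```

meaning RR's leave-one-out predictions explain ≈ 48% of the among-accession
shape variation of this 60-accession simulated collection (Q² = 1 would be
perfect prediction of every average contour; Q² ≤ 0 no better than
predicting the grand-mean shape). Per-accession squared shape errors land in
`demo/cv/*_errors.csv`. The same workflow runs on real data: a genotype CSV
(accessions × markers, scores in [−1, 1]) plus either a 77-column descriptor
CSV or `grainshape extract` applied to a directory of binary grain-mask
images. `grainshape fit` / `predict` serialize a model and predict
descriptors and reconstructed contour coordinates for new genotypes;
`grainshape compare` runs the exact paired Wilcoxon test between two
ten-fold CV reports.

The same API is available from Python (`grainshape.simulate_dataset`,
`grainshape.run_cv`, …); see `docs/methods.md` for the model details and
assumptions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates, from a fresh synthetic grain contour, the two structural
quantities of the descriptor machinery — the standardized descriptor length
at N = 20 harmonics and the post-standardization first-harmonic coefficient
a1 — and writes them as JSON.
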