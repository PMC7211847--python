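# Methods

## Estimand and estimator

For a trait z measured on clonally related cells, broad-sense heritability
H² is estimated as the slope of an ordinary least-squares regression of y on
x, where (x, y) are the trait values of pairs of relatives:

    H² = Cov(x, y) / Var(x).

This is a clonal adaptation of parent–offspring regression.  It is applied
to three relationships within each tracked family:

* **mother–daughter** — x is a complete mother's trait, y the mean over her
  complete daughters;
* **sister–sister** — both daughters of one division;
* **cousin–cousin** — granddaughters of the same cell through different
  daughter branches.

Sister similarity mixes stable lineage factors with transient effects of
shared cytoplasm at division; cousins never shared cytoplasm, so the cousin
slope reflects stably inherited variation only.  Estimates are computed per
cell line / dataset, never pooled.  Significance is a two-sided t-test on
the slope with n − 2 degrees of freedom; no multiple-testing correction is
applied, matching the per-relationship presentation of the report table.
A linear mixed / variance-component model is deliberately out of scope: with
few families per well and strongly unbalanced family sizes the simple
regression is the more transparent choice, and it is what the report
quantifies.

### Pairing policies

The regression requires choices the trait definitions do not fix; both
options are implemented and switchable, with deterministic defaults:

* **Sister orientation** (`first` | `double_entry`).  Default: x is the
  first-tracked sister (lower cell id).  `double_entry` enters each dyad in
  both orientations, making the slope orientation-invariant; its inference
  then counts unique dyads (df = n_dyads − 2, with the slope SE rescaled to
  that df) to avoid pseudo-replication.
* **Cousin pairing** (`branch` | `focal`).  Default `branch` emits one point
  per grandmother with complete cells in both granddaughter branches,
  x and y the branch means — no cell is reused across points.  `focal` emits
  one point per complete granddaughter against the mean of her cousins (the
  literal "mean of relatives" reading); it reuses cells across points, which
  leaves the slope unbiased but makes row counts larger than the number of
  independent units.

Minimum fit size is 3 pairs (one residual degree of freedom); a pair set
with Var(x) = 0 is rejected as degenerate rather than fitted.

## Traits and inclusion rules

Generation time T is (last frame − first frame) × frame interval, in hours,
from cytokinesis to cytokinesis.  Curvilinear speed is the total Euclidean
polyline length of the recorded path (microns) divided by T (µm h⁻¹).
Coordinates stay in pixels through parsing; the microns-per-pixel scale is
applied only in the traits module and must be supplied explicitly (tracking
files do not carry it).

A cell contributes to heritability estimation only if its full cycle was
observed: it needs a tracked mother whose track ends at the cell's first
frame (the shared division frame anchors both lifespans, counted once, in
the daughter) and must itself divide on screen.  Founders, off-screen exits,
deaths and cells still undivided at the end of the recording are excluded
but keep flagged rows; off-screen cells' partial-lifetime speeds feed only
the off-screen sampling-bias t-test.  A cell that divided but whose
daughters were not tracked still counts as complete — completeness is about
observing the cycle, not the descendants.  Gaps in a track contribute one
straight segment across the gap, so path length (and hence speed) is a lower
bound there; no interpolation points are invented.

Auxiliary checks mirror the design-quality tests a tracking study needs:
Welch two-sample t-tests of speed across family-size classes and between
off-screen and complete cells (a difference would indicate biased loss of
fast cells), Kruskal–Wallis on speeds across wells (spatial effects would
inflate familial similarity), and a Spearman correlation between speed and
generation time.  All tests are two-sided; the unequal-variance t form is
used throughout.

## Generative model of the simulator

Each trait is additive Gaussian on a binary pedigree:

    z = mu + g + s + u

with g the stable heritable component transmitted as an AR(1)
(g_daughter = a·g_mother + δ, δ ~ N(0, σ_δ²); founders draw from the
stationary N(0, σ_g²), σ_g² = σ_δ²/(1 − a²), so g-variance is constant
across generations), s a sister-shared transient drawn once per division and
given to both daughters (~ N(0, σ_s²)), and u independent noise
(~ N(0, σ_u²)).  An optional correlation parameter couples the u components
of speed and generation time; by default the traits are independent.  Draws
are truncated below at positive floors (speed > 0; generation time ≥ two
frame intervals) by clipping; default regimes keep the floors ≥ 3.3σ from
the mean so well under 0.1% of draws are affected and the induced bias is
far below Monte-Carlo resolution at the test sizes used.

With σ_z² = σ_g² + σ_s² + σ_u², the expected regression slopes are

    mother–daughter:  a·σ_g² / σ_z²
    sister–sister:    (a²·σ_g² + σ_s²) / σ_z²
    cousin–cousin:    a⁴·σ_g² / σ_z²

The mother–daughter and cousin forms hold exactly when Var(x) = σ_z², i.e.
when the regressor is a single cell: the mother, or a focal granddaughter.
Under `branch` cousin pairing the regressor is a mean of b sisters, whose
variance is (σ_z² + (b−1)(a²σ_g² + σ_s²))/b < σ_z², so the branch-mode slope
exceeds a⁴σ_g²/σ_z² when branches hold two complete sisters.  Parameter-
recovery tests therefore use focal mode, where the closed form is exact;
the pipeline default remains branch mode because it never reuses cells.

### Default parameters

Defaults describe a fibrosarcoma-like line tracked every 20 min for 72 h
(217 frames), 6 wells × 5 fields assigned round-robin, 110 founders,
0.65 µm/pixel:

| parameter | speed | generation time |
|---|---|---|
| mu | 37.55 µm h⁻¹ | 14.22 h |
| total SD σ_z | 10.03 | 4.15 |
| a | 0.9 | 0 |
| σ_g² | 50.30 (50% of σ_z²) | 0 |
| σ_s² | 21.64 | 7.75 (45% of σ_z²) |
| σ_u² | 28.66 | 9.47 |
| floor | 0.5 µm h⁻¹ | 2 frame intervals |

The speed decomposition reproduces the strongly heritable motility pattern
(expected slopes ≈ 0.62 sister, 0.45 mother–daughter, 0.33 cousin); the
generation-time decomposition has no stable component, so only sisters are
expected to correlate — the signature of transient cytoplasmic or
nutritional similarity in a fitness-coupled trait.  Censoring defaults are
5% off-screen and 1% death per non-founder cell, with the truncation frame
uniform over the cell's interior lifetime; cells whose division falls after
the last frame are censored by the recording end, and descendants of any
censored cell are dropped.

### Track realisation

Tracks are persistent random walks on the frame grid.  Every step has
length exactly speed × frame interval, so the computed curvilinear speed
recovers the generating trait to floating-point precision, and the number
of steps is the generation time rounded to the grid, so observed generation
times match generating values to within half a frame.  Headings evolve by
Gaussian increments with SD 1/√κ (κ = `turning_kappa`, default 5): κ → ∞ is
ballistic motion, κ = 0 draws each heading independently (diffusive limit,
MSD = n·L²).  A daughter's first point is her mother's last (division
anchoring).

### Reproducibility

Trait and censoring draws are family-major rows of single block draws from
spawn-keyed generator streams, so increasing the founder count appends
families without changing earlier ones; each trajectory has a per-cell
substream.  Identical configuration and seed give byte-identical output
files.

## What the simulator does and does not emulate

It reproduces the statistical structure the estimator assumes — family-
correlated traits with distinct heritable and sister-shared channels,
binary-division pedigrees over three generations, grid sampling,
incomplete observation — and the study-scale family counts.  It does not
model mechanistic cell biology (cell-cycle checkpoints, contact inhibition,
chemotaxis, spatial interactions between cells), trait drift within a
lifetime, or tracking errors (identity swaps, missed divisions).  Passing
recovery tests therefore shows the estimator is correct under the stated
model, not that real tracking data satisfy that model; on real data the
cousin-vs-sister comparison is exactly the lever for judging how much
similarity is stable rather than transient.

## Numerical and validation choices

* The OLS fit is cross-checked in tests against an independent
  sums-of-products Cov/Var computation (agreement to 1e−12), and the rank
  and rank-sum statistics against hand-coded oracles.
* Parameter recovery compares replicate-mean slopes (100 replicates × 2000
  families per parameter set, spanning a ∈ {0, 0.5, 0.9, 0.99} and both
  trait regimes) to the closed forms within 3 Monte-Carlo standard errors
  of the replicate mean; replicate spread is used rather than the OLS slope
  SE because family structure makes pairs dependent.
* Null calibration: with σ_g² = σ_s² = 0 the slope t-test rejects at
  3–7% over 1000 replicates of 300 families at α = 0.05.
* Sample-mean checks on simulated data use cluster-robust (family-level)
  standard errors, again because family members share latent components.
* Report SDs are per-cell standard deviations over complete cells (ddof 1),
  labelled as such; whether a family-mean SD would be preferable is a
  reporting convention, not an estimation issue.
* Problem sizes in tests (40–2000 families; 10⁴–10⁵ replicates for
  geometric oracles) were chosen so Monte-Carlo bands resolve the effects
  being checked while the full suite stays fast on one CPU.

## Known limitations

* The slope SE reported for a single dataset treats pairs as independent;
  within-family dependence (several dyads per family) makes it slightly
  optimistic.  The report's per-relationship p-values inherit this, as does
  any simple-regression presentation of such data.
* Track gaps bias path length (hence speed) downward; the bias is
  documented, not corrected.
* Truncation at trait floors is clipping, not resampling; extreme
  parameter regimes (mean within ~2σ of the floor) would bias both means
  and slopes and are outside the tested envelope.
* The MDF dialect reader covers the Assembly/Cluster/Track/Point layout
  with one channel and ignores z; pedigree information always comes from
  the lineage CSV sidecar because the MDF format carries none.
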