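# Methods

This note documents the models and procedures implemented in `sltp`, the
choices made where the design was genuinely open, and what the synthetic
phantom study can and cannot show.

## Spatial model: the Poisson distance conformal map

The lung shape is encoded by the solution of `ΔU = −1` inside the lung mask
with `U = 0` on the boundary, normalized to `max U = 1`. Discretely we use
the 7-point Laplacian with physical (mm) spacing, Dirichlet zero on the
boundary shell (mask voxels touching the outside) and implicitly outside.
Systems up to 60 000 unknowns are factorized directly; larger ones are
solved by conjugate gradients (relative tolerance 1e−12, direct fallback),
which is well below discretization error. A red–black Gauss–Seidel
implementation serves as an independent reference in tests. When the
solver is validated against the closed-form ball solution
`U(r) = (R² − r²)/6`, the ball is digitized as voxel centers within
`R + h/2`, so the zero-clamped boundary layer straddles the nominal surface
— with centers-within-`R` digitization the discrete Dirichlet surface sits
half a voxel too deep and the comparison measures digitization bias rather
than solver quality.

Per-slice calibration (`U_2d`, `U_mod`) prevents the field maximum from
collapsing onto a single depth-dependent core. The per-slice maximum
profile is smoothed with a 5-slice moving average; a local maximum is a
value strictly greater than its nearest unequal neighbors (plateau ends
qualify, array ends count as −∞). The band `[i_u, i_d]` between the first
and last local maxima is forced to contain the 25%–75% cumulative-volume
slices (counted from the apex). Outside the band, the fixed scalers can
push values above 1, so `U_mod` is clipped at 1 to keep `r = 1 − U_mod`
non-negative. Empty apical/basal slices are skipped.

The angular coordinates are spherical angles about the core voxel (the
`U_mod = 1` voxel on the mid-volume slice nearest the in-plane centroid,
ties to the smallest row-major index): θ is the axial-plane azimuth with
θ = 0 anterior, increasing toward the lateral side of each lung (the left
lung's x-axis is mirrored so the medial/lateral sectors are homologous),
and ϕ is the elevation, positive toward the apex. The map is "conformal"
only in the loose sense of a continuous sphere-like parameterization; no
angle-preserving surface parameterization is attempted.

## Features

- **Emphysema gates.** `%emph₋₉₅₀` thresholds at −950 HU. The spatially
  coherent alternative is a two-component Gaussian intensity mixture fit by
  EM inside the lung, smoothed by iterated conditional modes with a
  six-neighbor contiguity weight (β = 1, 5 sweeps). This is a synthetic
  stand-in with the qualitative behavior of measure-field segmentations
  (fewer isolated voxels than thresholding); degenerate fits fall back to
  thresholding. Training keeps ROIs with *both* measures > 1%; at labeling
  time a center with *either* measure ≤ 1% becomes no-emphysema (class 0) —
  the train/test gating asymmetry is intentional and kept as specified.
- **SURS.** The lung bounding box is tiled by 25 mm stacks (stack edge =
  ROI edge; the tiling rounds up, so edge stacks overhang the box). Each
  stack contributes β₂ lattice positions, each displaced by a uniform shift
  in [0, β₁] mm per axis; a candidate is kept iff its voxel center lies in
  the lung. With β₁ = 0 the draw is deterministic regardless of seed.
- **Textons.** The codebook is plain k-means (k-means++, fixed seed,
  ≤ 300 iterations, tol 1e−6) on raw 3×3×3 voxel patches in HU; ROI texture
  is the normalized histogram of nearest-texton counts over all stride-1
  patches. Patches are restricted to windows fully inside the lung mask
  (with an all-patches fallback for slivers too thin to hold one window):
  peel ROIs otherwise encode chest wall and outside air rather than lung
  texture, which measurably destroys class separability. The codebook is
  learned once on the training scans' gated ROIs and frozen for every
  subsequent feature computation — features compared against model
  centroids must live in the centroids' codebook space.
- **Spatial bins.** r in right-open thirds (core/mid/peel, r = 1 to peel);
  θ in four quadrants centered on the anatomical axes (edges at
  π/4 + k·π/2 so "anterior" is a 90° sector about the anterior direction);
  ϕ in thirds indexed superior → inferior. 36 sub-regions total; the flat
  index rasters r, then θ, then ϕ.

## Pattern learning

Initial LTPs are Lloyd-type k-means under the χ² histogram distance
(`½ Σ (p−q)²/(p+q)`, empty bins contribute 0) with k-means++ seeding and
arithmetic-mean centroid updates; empty clusters are dropped. Spatial
augmentation relabels each ROI to the admissible pattern (χ² texture
distance within the pattern's 95th-percentile intra-cluster spread, from
the previous iteration's assignments) minimizing
`χ² + λ·W·‖FS − F̄S‖²`, with a texture-only argmin fallback when every
pattern is barred. `W = SST_T / SST_S` rescales the two feature scatters.

The arithmetic mean is not the exact χ² centroid, so unconstrained
iteration eventually churns on a plateau with objective wiggles of order
1e−4 relative. Termination is therefore threefold: < 0.1% of labels
change, 50 iterations, or an iteration fails to improve the objective by a
relative 1e−6 — in the last case the previous (better) iterate is kept, so
the recorded objective trace is non-increasing. With the penalty active, a
small fraction of ROIs (the tail beyond their own cluster's P95 threshold)
can move even at λ = 0, so ΔSSW_T(0) is near but not exactly zero; the
exact λ = 0 fixed point holds with the penalty off.

λ* is the largest value on a 51-point grid over [0, 2] whose
ΔSSW_T < L_T = 1%; the whole (λ, ΔSSW_T) trace is retained.

## Merging

The replacement ratio `ratio_{i→j}` removes centroid i and relabels its
ROIs by the labeling cost over the remaining patterns, restricted to
patterns whose maximal intra-cluster texture distance the ROI does not
exceed; unrelabelable ROIs stay in the denominator (conservative edges).
Edges are the mean of the two directed ratios; weights strictly below 0.5
are removed. The pruned graph is partitioned by minimizing the two-level
map equation for undirected weighted graphs (node visit rates proportional
to weighted degree). The optimizer is greedy: Louvain-style single-node
moves to neighboring modules, followed by module aggregation, repeated to
convergence, with 10 seeded restarts keeping the best description length;
isolated nodes always stay singletons. An exhaustive search over all set
partitions provides the oracle for graphs up to 12 nodes in the tests. The
`infomap` reference implementation is not part of the environment, so the
map equation and its optimizer are implemented here directly.

Final sLTP centroids are means over the pooled member ROIs, indexed 1..N
by ascending mean ROI attenuation.

## Labeling

Test scans are labeled at SURS centers only (dense per-voxel features are
deliberately avoided); unlabeled lung voxels take the code of the nearest
(mm) sampled center within the same lung, per-lung because cross-lung
assignment under per-lung PDCMs is meaningless. Eq-cost ties break to the
lowest sLTP index. λ·W from training is reused at labeling time.

Cross-scanner calibration first shifts the source scan so its outside-air
mean matches the reference, then applies a 256-knot monotone
piecewise-linear quantile map estimated on normal parenchyma (applied
inside the lung, linear extrapolation beyond the knots). Outside air is
detected as sub −600 HU voxels outside the lung.

## Visualization

Angular projections average HU per (θ, ϕ) cell along r; radial projections
average over angles at `N_r = 60` regular radial bins; empty cells are
NaN-flagged, never zero-filled. Density plots bin r into `N_r`
isovolumetric bins (equal lung-voxel-count quantiles), keep at most
`α_i · N̄_IsoV` centers per bin (`α_i = r_i / r_{N_r}`, sampled without
replacement, seeded), project centers to the sagittal plane
(`r' = √(y²+z²)`, `ϕ' = atan2(z, y)` — the two-argument form, as the
single-argument arctangent loses the quadrant) and accumulate per-pattern
densities on a regular 40×40 grid over the occupied range. The
label-share-weighted sum of densities is algebraically 1 in every
non-empty cell and is asserted as such.

## Evaluation statistics

Cluster matching is the Hungarian assignment on the (zero-padded) overlap
matrix; `R_ln` averages the matched recovery fraction of each reference
cluster over retrained models, skipping empty reference clusters with an
adjusted divisor. Planted-class recovery uses majority-vote (many-to-one)
grouping of discovered patterns onto the planted classes before computing
the adjusted Rand index — a one-to-one matching cannot group a finer
clustering onto three classes. Label-map reproducibility is the mean
per-pattern Dice across scans plus the Spearman correlation of per-scan
pattern percentages; cross-session agreement is Cohen's κ of pattern
presence (NaN for degenerate tables).

The signature regression `argmin_A ‖XA − Y‖²` with `A ∈ [0,1]` and unit
row sums (the strict inequalities of the formulation are relaxed to closed
bounds; interior optima coincide and boundary optima are the feasible
limit) is solved with SLSQP (analytic gradient, ftol 1e−10) and scored by
ICC(2,1) — two-way random effects, absolute agreement, single measures —
via `pingouin`, with 4-fold cross-validated predictions. Identical
prediction/truth vectors return ICC = 1 directly because the F statistics
degenerate there. ICC pairs are compared by Fisher's r-to-z with
`z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3))`.

## The phantom study

Each phantom embeds two mirrored ellipsoidal lungs (half-axes
32 × 52 × 88 mm, 30% apical in-plane tapering) in a ≥ 16 mm soft-tissue
body (40 HU) surrounded by air (−1000 HU) on a 96 × 80 × 112 grid at 2 mm
isotropic spacing. Parenchyma is N(−850, 30²) HU noise, spatially
correlated by a 0.7-voxel Gaussian and rescaled to σ = 30; the whole
volume gets a final 0.5-voxel smoothing as a point-spread stand-in. The
16 mm wall matters: with a thin wall, 25 mm ROIs at the pleura reach
outside air, which is indistinguishable from emphysema in HU.

Three planted classes occupy disjoint sub-region sets of both lungs
(defined on each phantom's own PDCM):

| class | texture | region | composition | mean HU |
|---|---|---|---|---|
| 1 | blob-sparse | superior, anterior+lateral | 30% blobs of −1000 HU (3 mm scale) on −880 HU | −916 |
| 2 | blob-dense | mid-level, posterior+medial | 60% blobs of −1000 HU (7 mm scale) on −820 HU | −928 |
| 3 | diffuse-uniform | inferior, anterior+posterior | uniform −975 HU | −975 |

Blob geometry comes from thresholding smoothed Gaussian fields at the
class quantile; a bright-reticular (fibrosis-like) kind thresholds the
field near its zero level set into strands. Class contrast was set so the
generator meets its own separability requirement (between-class texton
distances well above within-class) under the σ = 30 noise; weaker
contrasts do not.

**Problem sizes.** The study runs as a five-phantom cohort (four training
scans with ±8% lung-geometry jitter, one held-out labeling scan), with
`n_ltp = 6` and training `β₂ = 10` — against cohort defaults of
`N_LTP = 100`, `β₂ = 3`. The scaled values keep cluster occupancy
(~300 ROIs per initial pattern) in the same regime as full-cohort
training; six initial patterns give the three planted classes plus
boundary mixtures room without fragmenting. Training on a single phantom
is measurably unstable under 25% subsampling (too few ROIs), which is a
data-size effect, not an algorithmic one; the cohort design mirrors the
leave-25%-of-scans-out protocol at desk scale. Reproducibility of sLTP
learning is evaluated scan-wise: four retrained models (each with one
training scan eliminated) label the held-out scan's gated ROIs and are
Hungarian-matched to the full model's labeling.

**What the phantoms do not emulate.** Airways, vessels, lobar fissures,
reconstruction-kernel texture, scanner drift, cardiac motion and genuinely
continuous disease severity are all absent, and the planted classes are
crisper than real emphysema subtypes. Passing tests therefore demonstrate
the pipeline's internal correctness and its recovery behavior under
favorable contrast at desk scale — not clinical performance. Quantities
tied to cohort-scale data (the published pattern count, reproducibility
and ICC levels) are not reproducible here and are not asserted.

## Numerical conventions

Degenerate inputs fail loudly (empty masks, interior-free masks,
non-stochastic mixing matrices, rank-0 predictors) or fall back with a
logged warning where the pipeline can continue (flat calibration profiles,
degenerate intensity mixtures, empty normal-parenchyma masks). All
randomness flows from one integer seed through CRC-keyed child seeds per
stage, so stages are independently reproducible and a full run is
deterministic — including the CG solve, k-means, SURS draws, ICM and the
merge restarts.
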