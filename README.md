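# sltp — spatially-informed lung texture patterns for emphysema subtyping

`sltp` implements an unsupervised pipeline that discovers emphysema
subtype candidates — *spatially-informed lung texture patterns* (sLTPs) —
from full-lung CT scans, and exercises it end to end on synthetic lung
phantoms with known planted texture classes.

Pulmonary emphysema appears on CT as regions of abnormally low attenuation
(approaching air at −1000 HU), and its standard subtypes (centrilobular,
panlobular, paraseptal) differ in both *texture* and *location* within the
lung. The pipeline therefore learns patterns jointly in texture and space:

1. **Poisson distance conformal map (PDCM).** For each lung mask `V`, solve
   `ΔU = −1` in `V`, `U = 0` on `∂V`. After per-axial-slice calibration the
   field `U_mod` yields a radial coordinate `r = 1 − U_mod` ("peel to core")
   and azimuth/elevation angles `(θ, ϕ)` about a core voxel, giving every
   voxel a standardized address comparable across subjects.
2. **ROIs and features.** 25 mm ROIs are drawn by systematic uniform random
   sampling (SURS; `β₁` random shift, `β₂` samples per stack), gated to
   emphysema-like lung (`%emph₋₉₅₀ > 1%` and `%emph` from a spatially
   coherent segmentation `> 1%`). Texture is a 40-bin texton histogram
   (k-means codebook of 3×3×3 patches), space a one-hot vector over 36 lung
   sub-regions (3 radial × 4 azimuthal × 3 elevation bins).
3. **LTP learning.** 100 initial lung texture patterns (χ²-k-means on
   texture histograms) are spatially augmented by iterating assignments
   under the mixed cost
   `χ²(FT_x, F̄T_k) + λ·W·‖FS_x − F̄S_k‖²`, with an infinite penalty against
   joining a pattern whose 95th-percentile texture spread the ROI exceeds.
   `W` balances texture and spatial scatter; `λ` is the largest grid value
   in [0, 2] whose texture-homogeneity loss ΔSSW_T stays below 1%.
4. **Merging.** The LTP graph weighted by average replacement ratios
   (fraction of a pattern's ROIs absorbed by another when the first is
   removed), thresholded at 0.5, is partitioned by minimizing the two-level
   map equation; each community becomes one sLTP, indexed by ascending mean
   attenuation.
5. **Labeling and evaluation.** Scans are labeled at SURS centers (gated
   centers → class 0, the rest by the mixed cost) and completed by
   nearest-center Voronoi fill; per-scan signatures, reproducibility metrics
   (Hungarian-matched R_ln, Dice, Spearman, Cohen's κ), sagittal density
   plots and a constrained regression onto standard-subtype extents
   (`argmin_A ‖XA − Y‖²`, `A` row-stochastic in [0, 1], scored by ICC)
   round out the toolkit.

Because no clinical cohort ships with the package, a first-class phantom
module generates lungs with planted, ground-truthed texture classes, so
every stage is verifiable.

## Worked example

```python
import numpy as np
from sltp.merge import merge_ltps
from sltp.phantom import truth_class_of_centers
from sltp.pipeline import (build_cohort, child_seed, cohort_training_table,
                           fit_ltps, phantom_study_config)
from sltp.evalstats import matched_ari

config = phantom_study_config(seed=1)
cohort = build_cohort(config, n_scans=5, seed=1)      # ~3 min on one core
train = cohort_training_table(cohort["scans"], [f"scan{i}" for i in range(4)])
tr = fit_ltps(train.ft, train.fs, config, seed=1)
sltp, graph, part = merge_ltps(tr.model, train.ft, train.fs, train.mean_hu,
                               seed=child_seed(1, "merge"))
truth = np.concatenate([
    truth_class_of_centers(s.table.subset(s.table.gated).centers,
                           s.bundle["truth_labels"].voxels)
    for s in cohort["scans"][:4]])
print("n_sltp =", sltp.n_sltp)
print("lambda* =", round(tr.lam_star, 2))
print("ARI =", round(matched_ari(sltp.labels[truth > 0], truth[truth > 0]), 3))
```

prints

```
n_sltp = 6
lambda* = 1.04
ARI = 0.894
```

i.e. the pipeline discovers six patterns on the four-phantom training
cohort, the data-driven spatial weight settles at λ* = 1.04, and grouping
the discovered patterns onto the three planted classes recovers them with
an adjusted Rand index of 0.89.

A single-scan run with artifacts on disk is also available from the shell:

```bash
sltp pipeline --seed 3 --out run/     # phantom → PDCM → train → merge → label
sltp pdcm --mask run/lung_right.nii.gz --side right --out run/pdcm/
```

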