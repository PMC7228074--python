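# Methods

## Overview

`gliotex` classifies gliomas as low-grade (LGG) or high-grade (HGG) from
two conventional MRI contrasts (post-contrast T1-weighted `T1Gd` and
T2-weighted `T2`) using texture features of the gray level size zone
matrix (GLSZM) computed inside segmented tumor regions, and linear models
built by an under-sampling ensemble procedure. This note records the
model, its assumptions, the numerical choices, and what the synthetic
cohorts do and do not demonstrate.

## Input assumptions

Volumes are assumed co-registered, resampled to 1 mm isotropic,
skull-stripped and bias-field corrected upstream; the package starts at
intensity normalization. Segmentation masks use integer labels
1 = NCR/NET (necrotic and non-enhancing tumor core), 2 = ED (peritumoral
edema), 4 = ET (enhancing tumor), 0 = background; the label map is the
BRATS convention. ET is deliberately not offered as a feature source
because it is absent in a meaningful fraction of LGGs.

## Intensity normalization

Raw intensities are standardized by landmark (Nyúl-style) histogram
matching to an integer 0–255 scale, 0 reserved for "absence of a value"
(background). Choices:

- **Landmarks**: 1st and 99th percentile cutoffs plus deciles 10–90. This
  is the standard configuration of the landmark method; the exact landmark
  set is a free parameter of the approach, so level-exact agreement with
  any other implementation is not guaranteed.
- **Reference volumes**: per (contrast, grade, dataset group) stratum, the
  volumes with the lowest and highest mean brain intensity, the mean
  computed over nonzero voxels outside all tumor labels — the tumor
  environment is too heterogeneous to anchor a scale. Ties break to the
  lexicographically smallest glioma id (determinism). Reference gliomas
  are excluded from all further analysis; the split module therefore
  expects a post-exclusion cohort.
- **Landmark estimation for any volume** likewise excludes tumor voxels,
  extending the reference-selection rationale; the learned map is then
  applied to *all* brain voxels, tumor included.
- **Mapping**: each reference's landmarks are affinely sent so the
  1st/99th cutoffs land on 1/255; mapped landmarks are averaged across
  references into the standard positions. A volume is normalized by the
  piecewise-linear map from its own landmarks to those positions, rounded,
  and clamped to [1, 255]. Values beyond the cutoffs clamp rather than
  extrapolate, so 0 stays reserved. Duplicate landmark values (possible on
  discrete-valued input) are collapsed to a single knot with the mean
  target position, keeping the map monotone; a constant volume is an
  error. Because of this collapsing, learned landmark positions are
  validated as non-decreasing rather than strictly increasing — strict on
  continuous-valued input, where the distinction never arises.

## GLSZM and texture features

A *zone* is a maximal 26-connected (3D; 8-connected in the 2D fallback)
set of voxels sharing one gray level inside the chosen region. The matrix
`s(i, j)` counts zones of level `i` and size `j`; `N_s` zones, `N_v`
region voxels with intensity ≥ 1. Conservation (`Σ j·s(i,j) = N_v`,
`Σ s(i,j) = N_s`) is asserted on every constructed matrix. Connected
components are labeled with `scipy.ndimage.label` under a full
connectivity structure; the matrix is stored sparsely because zone sizes
can reach the region size.

Gray levels are the normalized integers themselves — no re-binning by
default — since the normalization step already quantizes to 255 levels.
An optional equal-width re-binning is not provided as a separate operation;
callers may quantize before matrix computation if desired.

The 13 features follow the standardized `F_szm.*` definitions (small/large
zone emphasis, gray-level and zone-size nonuniformity, zone percentage,
low/high gray-level emphases and their small/large-zone crosses,
gray-level and zone-size variance); formulas are in the `features` module
docstring. `i` in gray-level-weighted features is the intensity value
itself (the bin index when unbinned). Features enter regression raw —
unstandardized — because the published coefficients act on raw feature
values.

## Data division and the ensemble

From `n_LGG` and `n_HGG` gliomas, one fixed testing subset (34 + 34 by
default) is drawn, then 100 training subsets of 30 + 30. The LGG training
block is drawn once and shared (in the canonical 64/191 cohort it is
exactly the 30 LGGs left after the testing draw); HGG members are
independently re-drawn per subset. When more LGGs remain than the block
size, one fixed block is drawn and reused, generalizing the shared-block
structure. All draws are without replacement within a subset and
deterministic under the split seed.

Per subset, features are compared between classes with the two-sided
Wilcoxon rank-sum test — normal approximation with tie and continuity
corrections (`scipy.stats.mannwhitneyu`, asymptotic), the standard choice
at 30 per group; fully tied samples give p = 1. Features are ordered by
ascending p and truncated at p < 0.05 (configurable); `D_i` features
survive in subset `i` and `d = min_i D_i`. Position-wise histograms over
subsets give the ordered highest-frequency features `x_1..x_d`; a
histogram whose winner was already chosen falls through to its next most
frequent unchosen feature. Deterministic tie-breaks: within-subset p-value
ties break lexicographically on the feature id; histogram frequency ties
break by lower mean p across subsets, then lexicographically. If every
feature of a later histogram is already chosen (possible in principle,
never observed in practice), the unchosen feature with the highest total
frequency across all position histograms is taken, so the consensus always
has `d` distinct entries. A combination with `d = 0` is excluded from
modeling.

## Models

For model size `t ≤ d`, the `w` training subsets whose first `t` ordered
features *coincide* with `x_1..x_t` are selected. "Coincide" is
interpreted as **set** equality over the leading positions (default): the
reduced-model selection rule treats the leading variables as an unordered
group, and the same reading is applied to unique models for consistency.
Order-exact matching is available via `match_order`. Each selected subset
gets an ordinary least-squares fit against targets −10 (LGG) / +10 (HGG)
(`numpy.linalg.lstsq`; rank-deficient designs are an error; the solution
matches an explicit normal-equations solve to 1e-8 on well-conditioned
inputs). Coefficients, intercept included, are averaged across the `w`
fits. By linearity, the averaged model's prediction equals the mean of the
member models' predictions — asserted in tests to 1e-8.

The best model is the one with the highest testing accuracy, then the
lowest clipped MAE, then the fewest variables. Reduced models are built
for every non-empty subset `C` of the best model's variables: with
`m = max(C)`, qualifying subsets are those whose first `m` features match
`{x_1..x_m}` as a set; only the variables in `C` are fitted, then
averaged. A `t`-variable best model yields `2^t − 1` reduced candidates
(7 for three variables, 31 for five — all of them are generated; accounts
that report 30 for five variables omit one combination without saying
which). The final reduced choice takes the highest accuracy, then the
fewest variables, then the lowest MAE — smallness is the point of the
reduction, so it outranks the error term here.

Inner fits in the ensemble and reduction loops run through a small design
cache that resolves subset rows and class targets to plain arrays once;
this is a performance detail with no effect on the numbers.

## Classification and metrics

`ŷ < 0` calls LGG, `ŷ ≥ 0` HGG; exactly zero is a measure-zero event and
is assigned to HGG, the clinically costlier class to miss. HGG is the
positive class: sensitivity = TP/(TP+FN) over HGGs, specificity =
TN/(TN+FP) over LGGs; percentages are reported to 2 decimals. The mean
absolute error is *clipped*: an LGG predicted below −10 or an HGG above
+10 has already exceeded its ideal and contributes zero, so only
shortfalls toward the decision boundary count; the MAE is therefore
bounded in [0, 20].

The packaged published classifier
`ŷ = 13.693·F_szm.z.perc(T2,NCR/NET) − 0.410·F_szm.zs.var(T2,NCR/NET)
+ 31.842·F_szm.zsnu(T1Gd,NCR/NET) − 19.500` ships as a JSON asset and is
loadable by name (`published_model()`, CLI `--model published`).

## Synthetic cohorts

The generator emulates the two properties downstream stages depend on,
and nothing else:

- **Volume cohorts**: an ellipsoidal brain, a central spherical NCR/NET
  core covering `region_fraction` of the grid, and a 2-voxel dilated ED
  shell. Texture is laid down by nearest-seed (Voronoi) labeling of
  Poisson-seeded points with mean spacing equal to the characteristic zone
  edge length, each cell mapped to a uniform gray level in `1..gray_levels`
  (8 by default), followed by per-voxel relabeling noise
  (`noise_prob = 0.05`). Zone scale is set per (grade, contrast); defaults
  make HGG cores coarser on T1Gd and LGG cores coarser on T2, mirroring
  the contrast-dependent heterogeneity the method detects. Default grid
  32³ keeps volume tests in seconds. Not simulated: MRI physics, bias
  fields, partial-volume effects, registration artifacts, anatomical
  variability — so passing volume tests shows the *machinery* is correct,
  not that real scanners produce these distributions.
- **Feature tables**: the fast path plants class-conditional Gaussian
  shifts directly in named feature columns (LGG ~ N(0,1), HGG shifted by
  the stated effect in σ units). Default cohort size 64 LGG / 191 HGG,
  the canonical post-exclusion imbalance. The recovery benchmark plants
  one 3σ feature per contrast in the NCR/NET sources; under this setting
  the edema-only combinations are excluded with d = 0 and the ensemble
  recovers the planted features with ≥ 90 % testing accuracy. Under the
  null (no shifts), d = 0 for essentially all combinations — the minimum
  over 100 subsets of a Binomial(13–52, 0.05) count is almost surely
  zero — so null runs mainly demonstrate the exclusion rule; the
  near-chance-accuracy check applies only to the rare surviving model.

Gaussian features ignore the dependence structure of real radiomic
features (which are strongly correlated within a matrix); consensus
behavior under correlated nulls is not characterized here.

## Reproduction script

`scripts/acceptance.py` recomputes, from scratch and under a single seed:
the published model's arithmetic on unit/zero inputs, the 15-combination
enumeration, ensemble recovery metrics on a fresh 64/191 planted cohort
(full 100-subset protocol), the null exclusion fraction over 5 seeds, and
a volumetric run (24 LGG / 40 HGG at 24³, 10 + 10 testing, 30 subsets of
14 + 14) from voxels through GLSZM to a fitted model. The volumetric
problem sizes are chosen to exercise every stage at desk scale while the
full-size protocol runs on the feature path, where the statistical claims
live.

## Known limitations

- One fixed testing subset, as in the original design: results vary with
  the testing draw; no cross-validation is provided.
- No multiple-testing correction in the ranking stage (by design).
- Landmark percentiles of the original normalization implementation are
  unknown; intensity-level-exact reproduction of externally normalized
  volumes is not guaranteed.
- Segmentation is an input; the pipeline is supervised, not automatic.
- The consensus fallback for fully exhausted histograms is a documented
  extension of the procedure, chosen for totality and determinism.
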