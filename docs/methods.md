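# Methods

This note documents the models, the numerical choices, and the synthetic
data used to validate them — what the pipeline assumes, what its defaults
mean, and what passing tests do and do not demonstrate about real data.

## Spatial carrier

All rasters are north-up geographic (lat/lon, WGS84) grids with square cells
(`Grid`: values, nodata mask, origin, cell size). The on-disk form is the
ESRI ASCII grid — plain text, lossless enough at `%.8g`, and readable by any
GIS. Mixed-resolution inputs are aligned by bilinear resampling onto a
template; a resampled cell touching any nodata source cell, or outside the
source extent, becomes nodata. Bilinear interpolation reproduces linear
surfaces exactly, which the tests exploit as a closed-form oracle.

## Occurrence curation

- **Accuracy filter.** Records are retained when their positional
  uncertainty is *strictly* below the bound (default 5 km). Records with
  missing uncertainty are dropped by default; a non-strict mode keeps and
  flags them. The single bound is deliberate: sources with coarser
  native resolutions (e.g. 10-km grid data) can be admitted by raising it.
- **Spatial thinning.** Distances are great-circle (haversine) km — planar
  degrees would distort the 10-km rule with latitude. The thinning algorithm
  repeats `iterations` (default 1000) times: visit records in seeded random
  order, greedily accept each record ≥ 10 km from all accepted; the largest
  accepted subset wins, first-attained on ties. Records are canonically
  sorted by (lon, lat) internally, so the result is invariant to input
  order for a fixed seed; best-subset size is monotone non-decreasing in
  `iterations`. Randomized greedy is not guaranteed optimal, but on small
  instances (n ≤ 12) it matches exhaustive maximum-subset search in the
  test suite. Coincident duplicates need no special handling — thinning
  keeps exactly one.
- **Study area.** The union of planar-degree disks (default radius 2.5°)
  around presences, intersected with the template's valid cells. Planar
  degrees mirror the common buffer-on-unprojected-coordinates practice;
  the metric distortion with latitude is accepted and documented.
  Contiguity is emergent, never enforced.

## Predictor preparation and selection

- **Slope** comes from elevation by Horn's 3×3 finite-difference kernel,
  with 111,320 m per degree latitude and a cos(lat) correction for
  longitude; edge cells and neighbors of nodata cells are nodata. An
  independent central-difference gradient agrees within 10% on smooth
  synthetic terrain.
- **Collinearity.** VIF_j = 1/(1−R²_j) from regressing each variable on the
  others (least squares with intercept); perfect collinearity reports
  `inf`, never a silent clip. The pairwise filter then iterates: find the
  worst pair with |r| ≥ threshold (default 0.8), drop its member with the
  higher mean |r| against everything remaining. A keep-list protects
  variables chosen on ecological grounds (the automated mean-|r| rule
  replaces what is otherwise a manual expert step); a keep-list that is
  internally correlated above the threshold is an error the user must
  resolve. Statistics are computed on a seeded random sample of at most
  10,000 valid cells for tractability.
- **GCM selection.** Each candidate's study-area mean delta in two
  diagnostic variables defines a point; candidates are ranked by Euclidean
  distance to the across-candidate mean (the "ensemble point"). Raw units
  are the default — the variable pairs used in practice are of comparable
  magnitude — with a z-score option exposed; distance ties break on name so
  the ranking is permutation-invariant.

## Modeling

- **Design.** `n_sets` (default 5) independent draws of `n` (default 5000)
  pseudoabsence cells, uniform without replacement within the study area
  and never a presence cell; each set × `replicates` (default 10) seeded
  stratified 70/30 splits gives the 50-run design. Stratification
  guarantees both classes in both partitions (the unstratified alternative
  could produce one-class test sets at low prevalence). Pseudoabsence row
  weights equalize total class weight (prevalence 0.5), the convention of
  the ensemble platforms this mirrors.
- **Algorithms.** `SDMClassifier` wraps scikit-learn learners behind one
  suitability contract: GBM (`GradientBoostingClassifier`, defaults 2500
  trees, depth 7, learning rate 0.001, bag fraction 0.5), RF
  (`RandomForestClassifier`, 500 trees), GLM (`LogisticRegression`, linear
  terms), ANN (`MLPClassifier`, one hidden layer of 8). Defaults mirror
  platform conventions and are overridable; tests and the bundled profiles
  use reduced tree counts. The MLP ignores sample weights (sklearn does not
  support them there); since weights only equalize prevalence this biases
  its intercept, not its ranking, and ANN is an optional algorithm anyway.
  MARS is not provided (no maintained implementation in the dependency
  set); GLM+GBM+RF are the required core.
- **Evaluation.** Test AUC is the rank statistic (tied scores credit ½) —
  asserted equal to the brute-force concordant-pair fraction and to the
  library ROC implementation. The MTSS threshold maximizes
  sensitivity + specificity over candidates at midpoints of sorted unique
  scores plus {0, 1}; `score ≥ threshold` counts positive, ties go to the
  smallest maximizing candidate. Midpoint candidates are exact and
  scale-free, unlike a fixed 0…1 lattice.
- **Variable importance.** Permutation-based: shuffle one predictor column,
  re-predict, score 1 − max(0, r) where r is the Pearson correlation of
  original vs shuffled-input predictions, averaged over `n_perm` shuffles
  (default 1, the platform convention). Clamping negative r avoids
  pathological scores above 1. A zero-variance prediction vector yields 0
  with a warning. Per-species scores are averages across the ensemble's
  contributing models.

## Ensembling and change accounting

- Runs with test AUC > 0.8 contribute to an unweighted per-cell mean map;
  the contributing count is reported. The ensemble's MTSS threshold is
  computed from *ensemble* predictions on the pooled test partitions of
  contributing runs — a per-ensemble threshold matching platform ensemble
  workflows (the alternative, per-model thresholds, would not define a
  single binarization of the mean map).
- Per-GCM binary futures within one RCP are combined by cell-wise
  averaging; mean ≥ 0.5 counts suitable (inclusive, so exact ties in an
  even-sized ensemble count suitable — documented, and majority for the
  usual three GCMs).
- Range change uses the loss/stable/gain/never transition classes;
  percentages are relative to the present suitable area and rounded to one
  decimal, half away from zero; `pct_change` is rounded after differencing
  the unrounded percentages. The partition identities
  (loss+stable = present, stable+gain = future, all four = valid cells) are
  asserted on every computation.
- The elevation summary compares means and quartiles of altitude over
  presently suitable cells vs future-suitable cells (stable ∪ gain);
  `shift = future mean − present mean`.

## The synthetic case study

The generator produces the statistical structure the pipeline assumes,
not a simulation of any real climatology:

- **Layers** are linear mixes of shared smooth latent fields (white noise
  smoothed by a Gaussian kernel of width `autocorrelation_range` cells,
  standardized), rescaled exactly to per-layer means/sds. Inter-layer
  correlation equals the normalized inner product of loading rows, so a
  pair with |r| ≥ 0.8 can be planted to exercise the correlation filter.
  Kernel smoothing was chosen over spectral synthesis as simpler and
  dependency-light.
- **Terrain** is deterministic (plane, or a cone whose area shrinks with
  altitude — the usual montane hypsography) plus smooth roughness, so slope
  is nontrivial but analytically checkable on the deterministic part.
  Climate layers can be coupled to standardized elevation (a lapse-rate
  analogue).
- **The bundled case** (100×100 cells at 5 arcmin): three informative
  layers — summer temperature bio_10 (elevation-coupled, r ≈ −0.93),
  annual precipitation bio_12, temperature seasonality bio_4 — and three
  noise layers (bio_2, bio_17, bio_19) with realistic bioclim-scale units.
  The virtual species is cool-wet montane: μ = (12 °C, 1100 mm, 5500),
  σ = (2.5 °C, 250 mm, 1000). Breadths are set so each informative variable
  explains appreciable suitability variance (a σ comparable to the layer sd
  would make a response effectively flat, i.e. uninformative); mean true
  suitability lands near 0.10–0.15, so uniform pseudoabsences are mostly
  true absences. 300 presences are drawn without replacement with
  probability proportional to suitability.
- **Scenarios.** *Warming* (+2.5 °C bio_10, −100 mm bio_12): the thermal
  optimum is only found higher on the cone, where there is less area — the
  suitable envelope shifts uphill and contracts. *Wettening* (−1 °C,
  +150 mm): more of the landscape approaches the precipitation optimum and
  the envelope expands. Per-GCM deviations are smooth fields (scale 0.3
  layer units), mimicking coherent model disagreement rather than white
  noise. On the true-suitability side both directions hold at every seed
  probed; the discrimination ceiling (AUC of true suitability against
  uniform background) is ≈ 0.86, which bounds what any fitted model can
  achieve on this design.

**What passing does not show.** The generator has no sampling bias beyond
suitability weighting, no spatial bias in effort, no observation error in
coordinates, Gaussian (symmetric, unimodal) responses, and additive
scenario changes. Real occurrence data violate all of these; the tests
validate the *mechanics* of the pipeline (selection, thinning, evaluation,
accounting arithmetic, seeding), not SDM transferability in nature.

## Problem sizes and profiles

The test suite and the results-reproduction script run the bundled case at
reduced ensemble sizes chosen as the smallest that exercise the full
design: 2 pseudoabsence sets × 3 replicates of 150-tree forests with 1000
pseudoabsences for niche recovery and scenario contrasts, and one full
5 × 10 design at 5000 pseudoabsences (100-tree forests) for the model-count
bookkeeping. The shipped `configs/test_profile.yaml` (40×40 cells, 120
presences) lowers its AUC gate to 0.7: with so few presences individual
reduced-size models sit near AUC 0.75 against the ≈ 0.86 ceiling, and the
profile's purpose is to exercise the whole DAG, not to gate quality. The
study-scale defaults (`configs/study_defaults.yaml`) keep the 0.8 gate.

## Known limitations

- Tree-based learners do not extrapolate: when a scenario pushes predictor
  values beyond the training range, projected suitability flattens at the
  training-edge value. On some landscape seeds this makes the modeled
  wettening expansion smaller than the true-envelope expansion, or even
  negative, although the true envelope expands at every seed probed — the
  familiar transferability caveat of machine-learning SDMs under novel
  climates.
- Geographic grids only; no projected-CRS support, no categorical
  predictors, no dispersal constraint (projections assume unlimited
  dispersal), no spatial block cross-validation, no MaxEnt.
- The randomized greedy thinning is exact only empirically (verified
  against exhaustive search at small n); worst-case instances where 1000
  iterations miss the optimum by one record are conceivable.
- `combine_binary`'s inclusive ≥ 0.5 rule makes even-sized GCM ensembles
  lean suitable on exact ties.
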