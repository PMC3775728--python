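# Methods

## Model and procedure

The package analyzes inadvertent anterior choroidal artery occlusion
(AChAo) during intraluminal middle cerebral artery occlusion (MCAo) in the
rat, and its effect on 24 h infarct volume. Its components mirror the
experimental chain: perfusion-CT cerebral blood volume (CBV) maps →
threshold-based AChAo classification → histological infarct volumetry with
edema correction → cohort statistics. Because the original per-animal data
are not public, a first-class synthetic generator reproduces the study
conditions; every stage is tested both on constructed inputs and round-trip
against the generator's planted truth.

### Territory atlas

All spatial operations run on a parametric 2D coronal atlas. The default
grid is 128×128 voxels at the native CT in-plane scale (50 mm field of view
/ 512 matrix = 0.0977 mm/voxel), slice thickness 2.4 mm, slices at 0 and
−2.4 mm bregma; a full 512×512 grid is available through `GridSpec`. The
brain is an ellipse (semi-axes 0.42/0.45 of the grid), split at a midline
that falls between columns (`n_cols` must be even) so left and right masks
are exact mirror images. Cortex is the annulus beyond normalized radius
0.68; the MCA territory is a lateral sector (±40° about the horizontal,
normalized radius ≥ 0.25) spanning cortex and subcortex; the AChA territory
is a small medial subcortical disk (radius 0.04·`n_cols`, offset 0.12
laterally and 0.15 ventrally), present only on the caudal slice and carved
clear of the MCA sector so the two territories receive distinct perfusion
effects. No published pixel extent exists for the rat AChA territory; its
size is an exposed free parameter, not a measured value. Laterality is
explicit metadata (neurological convention by default), never inferred from
pixel order.

### Classification

Order of operations is fixed: large-vessel exclusion first (CBV strictly
greater than 10 ml/100 g; excluded voxels are flagged, never deleted), then
the mean contralateral CBV over surviving voxels, then the stringent
threshold (CBV ≥ mean, inclusive). "Lack of signal" is implemented as a
supra-threshold voxel count ≤ `tolerance_voxels`, default 0 (strict
absence); the tolerance is a parameter because no voxel-count leniency is
published. The call uses the caudal slice, where the AChA territory exists;
the contralateral mean is computed on that slice by default with a
pooled-across-slices option (the published description does not
disambiguate). The predicted-infarct threshold (2 ml/100 g) is strict
below-threshold; a voxel at exactly 2.0 is spared. The classifier is a pure
function of (maps, atlas, parameters) — the blinding of the original image
read is structural here.

### Volumetry

Section-to-volume integration is the simple sum of traced areas times the
section spacing (trapezoidal integration was considered and rejected: the
upstream quantification it emulates is a plain area×spacing sum, and the
choice is configurable in principle by resampling sections). Edema
correction multiplies the raw volume by contralateral/ipsilateral
hemisphere volume; it is homogeneous in the raw volume and invariant to
common rescaling of the hemisphere volumes. The cortical/subcortical split
intersects each section with the atlas masks of the nearest bregma level,
and the compartment volumes receive the same edema scale factor so they
still sum to the corrected total. Probability maps report the exact
fraction k/n of animals covering a voxel; the cosmetic rendering composites
n layers at 24% opacity, intensity 1 − 0.76^k, strictly increasing in k.

### Statistics

- Normality: the D'Agostino–Pearson K² omnibus test (squared normalized
  skewness and kurtosis transforms, χ² with 2 df), requiring n ≥ 8.
  Because the permanent-group cells (n = 6 and 7) are below that minimum,
  the gate runs at the widest feasible scope: per cell when both cells have
  n ≥ 8, otherwise on the group, otherwise flagged untestable. A failed
  test flags the comparison in the report (machine-readable warning); no
  rank-based fallback is substituted and the t statistic is still shown, so
  the report stays honest about what was computed.
- t-tests are Student's pooled-variance by default (the convention of the
  commercial statistics software this emulates), Welch available. A
  summary-statistics variant supports published mean ± SD inputs.
- Screening is marginal Pearson correlation at p < 0.10 (point-biserial on
  the binary AChAo indicator). Constant candidates are excluded with a
  warning rather than an exception, so degenerate cohorts (e.g. zero AChAo
  animals) degrade gracefully.
- Regression is ordinary least squares; standardized β is the coefficient
  times sd(x)/sd(y) with n−1 denominators (identical to fitting z-scored
  data); adjusted r² = 1 − (1−r²)(n−1)/(n−p−1). For a single predictor β
  equals Pearson r exactly.
- Permanent occlusion is coded 24 h on the duration axis by default (time
  from occlusion to euthanasia); an ordinal 1/2/3 coding is available. The
  published per-animal coding is unknown, so exact reproduction of the
  published r = 0.58, β = 0.732/0.367 and adjusted r² = 0.831 is not
  claimed; the pipeline's substituted check is sign-and-ordering recovery
  (β(AChAo) > β(duration) > 0) across seeded cohorts, which holds in ≥ 95%
  of 200 seeds under the default conditions.
- No multiple-testing correction is applied, matching the source analysis;
  the report states this.

## Synthetic data: what it emulates and what it does not

The generator reproduces the cohort structure (13 permanent / 8 one-hour /
7 two-hour animals; AChAo in 7/2/1), per-stratum infarct-volume
distributions, the CBV contrast pattern the classifier relies on, and
histology traces consistent with the recorded volumes.

- **Volumes** are drawn per stratum from normals truncated at zero
  (rejection sampling). The permanent strata use the published summaries
  (42.7 ± 27.62 and 144.5 ± 11.72 mm³). The 1 h/2 h strata have no
  published summaries; their default means are recovered by moment
  arithmetic from the published pooled and permanent summaries
  (non-AChAo: (18·24.6 − 6·42.7)/12 = 15.55 mm³; AChAo:
  (10·129.6 − 7·144.5)/3 = 94.83 mm³) with the pooled SD of the matching
  AChAo class, and the two temporary groups are treated as identically
  distributed — the printed data cannot distinguish them. Truncation
  shifts the low-mean strata upward; tests compare sample moments against
  a truncated-normal oracle, not the un-truncated parameters.
- **Cortical share** of each infarct is drawn around the published
  permanent-group ratios per AChAo class (59%/33%), SD 0.05, clipped to
  [0,1].
- **Weight** is uniform on 300–500 g and independent of volume, encoding
  the null weight finding.
- **CBV fields**: contralateral baseline 4.0 ± 0.3 ml/100 g per animal
  (typical grey-matter CBV), ipsilateral MCA territory at 30% of baseline,
  AChA territory at 10% when occluded and 120% when patent (the territory
  is visibly vessel-bright on real maps), five planted vessel voxels per
  hemisphere at 15 ml/100 g, Gaussian voxel noise SD 0.4 ml/100 g, clipped
  at zero. At these defaults the classifier recovers planted truth
  essentially always; at zero noise, exactly.
- **Histology traces**: eight sections at 2 mm spacing (positions chosen to
  include the −0.3 and −2.3 mm probability-map levels); section count and
  spacing are placeholders — the emulated protocol does not state them.
  Infarct masks are grown deterministically from the MCA-territory centroid
  of each compartment, allocating voxels across sections by
  largest-remainder apportionment, so mask volumes match the record to
  within one voxel volume per compartment and larger infarcts spatially
  nest smaller ones (which is what gives probability maps their graded
  core). Edema is modeled as uniform outward dilation of the ipsilateral
  hemisphere outline to contralateral × (1 + swelling fraction), default
  0.10; no swelling magnitude is published — the value only needs to
  exercise the correction formula, and hemisphere volumes (600 mm³ nominal)
  are likewise placeholders.
- **Reproducibility**: one seed expands into per-animal, per-product
  substreams via a stable CRC32 hash of the animal id, so records, maps and
  traces are reproducible independently and under reordering.

A deliberate design choice: trace masks match the record's volumes directly
and only the hemisphere outline is dilated. The pipeline's measured
corrected volumes therefore equal the record volumes times
contralateral/ipsilateral (≈ 1/1.1 by default) — a uniform scale factor
that leaves every scale-invariant statistic (r, t, standardized β)
untouched. The alternative (inflating the infarct with the swelling and
letting the correction undo it) would recover record volumes exactly but
hide the correction's effect; the current form makes it visible and
testable.

What the generator does *not* emulate: scanner physics and deconvolution
artifacts, spatially correlated noise, anatomical variability between
animals, partial-volume effects at territory borders, registration error
between histology and atlas, and collateral-flow hemodynamics. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis chain* under the assumed data model, not the field performance of
the thresholds on real CT perfusion maps.

## Numerical choices

- Thresholds: vessel exclusion is strict `>` 10 ml/100 g; the stringent
  threshold is inclusive `≥` mean contralateral CBV; infarct prediction is
  strict `<` 2 ml/100 g. Boundary conventions are asserted in tests.
- Voxels are wholly in or out of masks; volumes are exact voxel counts
  times voxel volume; degenerate inputs (empty contralateral ROI after
  exclusion, constant samples, n below test minima, infeasible requested
  volumes, rank-deficient designs) raise typed errors rather than returning
  NaN.
- Deterministic tie-breaks everywhere a selection is made (lexicographic
  (distance, row, column) ordering in region growth and dilation;
  largest-remainder with index order in apportionment), so outputs are
  bit-reproducible across runs; CSVs are written at 6 significant figures.
- Default problem sizes (128×128 grid, 28-animal cohorts, 200-seed property
  checks, 10⁴-draw moment checks, 10⁵-animal correlation simulations) were
  chosen so the whole suite exercises every stage at full fidelity while
  remaining quick on a single CPU.

## Known limitations

- The atlas is a geometric stand-in, not a registered stereotaxic atlas;
  territory sizes (especially the AChA blob) are free parameters.
- The 1 h/2 h stratum distributions are derived, not measured; treating the
  two temporary groups as exchangeable is an assumption.
- The published regression coefficients cannot be reproduced exactly
  without the per-animal data and duration coding; only directional and
  ordering properties are claimed.
- The classifier's noise robustness is characterized under additive
  Gaussian noise only.
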