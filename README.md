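# achastroke

Perfusion-CT cerebral-blood-volume (CBV) thresholding, anterior choroidal
artery occlusion calls, and edema-corrected infarct volumetry for the rat
middle cerebral artery (MCA) intraluminal thread-occlusion stroke model.

## The problem

Intraluminal thread occlusion of the MCA is the most widely used rodent
stroke model, and it is notorious for a dichotomous, highly variable infarct
volume distribution. A major driver is inadvertent co-occlusion of the
anterior choroidal artery (AChA), a small vessel arising near the MCA origin
whose territory is entirely subcortical but which also feeds the MCA
territory through anastomotic collaterals. Animals with combined MCA + AChA
occlusion infarct far more tissue — cortex included — than animals with MCA
occlusion alone.

This package implements, as a tested and reusable pipeline, the imaging and
statistical chain that detects AChA occlusion and links it to 24 h infarct
volume, together with a seeded synthetic generator that stands in for the
study's imaging and histology data (no raw data were deposited). It is aimed
at preclinical stroke researchers who want to reproduce the analysis,
stress-test its thresholds, or adapt the classifier to their own perfusion
maps.

## The method

For each animal, with CBV maps *V* (ml/100 g) on coronal slices at 0 and
−2.4 mm bregma:

1. **Large-vessel exclusion** — flag voxels with *V* > 10 ml/100 g; they are
   excluded from every downstream mean and count.
2. **Stringent threshold** — compute the mean CBV of the contralateral
   hemisphere, c̄, over non-excluded voxels; voxels with *V* ≥ c̄ are
   "signal".
3. **AChAo call** — the AChA is occluded iff its ipsilateral territory (on
   the caudal slice) contains no signal voxels. The call is blinded: a pure
   function of maps and atlas.
4. **Volumetry** — infarct volume from serial traced sections
   (Σ area × spacing), edema-corrected by
   `corrected = raw × contralateral / ipsilateral` hemisphere volumes, and
   partitioned into cortical/subcortical compartments; infarct probability
   maps (per-voxel fraction k/n, rendered as stacked 24%-opacity traces).
5. **Statistics** — D'Agostino–Pearson normality gate; two-tailed t-tests of
   MCAo vs MCAo+AChAo per occlusion group (groups whose smaller cell has
   n < 3 are not analyzed) and pooled; marginal Pearson screening of
   occlusion duration, AChA patency and weight at p < 0.10; multiple linear
   regression with standardized coefficients β and adjusted r².

A separate illustrative threshold (*V* < 2 ml/100 g) marks tissue predicted
to infarct.

## Worked example

```sh
python examples/05_cohort_statistics.py
```

prints (default synthetic cohort, seed 1):

```
group comparisons (MCAo alone vs MCAo+AChAo):
  1h        n=6/2  not analyzed: smaller cell has n=2 < 3
  2h        n=6/1  not analyzed: smaller cell has n=1 < 3
  permanent n=6/7    41.9 vs  150.2 mm^3  t=-11.61, p=1.6e-07
  pooled    n=18/10    27.8 vs  122.8 mm^3  t=-7.44, p=6.6e-08

predictor screening (include at p < 0.10):
  duration_h     r=+0.651  p=0.00018  included
  acha_occluded  r=+0.825  p=6.6e-08  included
  weight_g       r=+0.002  p=0.99  excluded

regression (n=28, adjusted r^2=0.817):
  duration_h     beta=0.413  p=8.1e-05
  acha_occluded  beta=0.681  p=4.2e-08
```

Reading: within the permanent-occlusion group, animals with the co-occluded
AChA infarct ~150 mm³ vs ~42 mm³ without it; weight carries no information;
and in the joint model AChA patency is the dominant independent predictor of
infarct volume (larger standardized β than occlusion duration). The two
1 h/2 h cells are too small to test, mirroring the study's small-cell rule.

The other examples cover the territory atlas (`01`), cohort simulation
(`02`), the blinded classifier (`03`, recovers planted truth 28/28),
volumetry and probability maps (`04`), and the full pipeline with
bit-reproducible CSV outputs (`06`). A thin CLI wraps the same library:

```sh
achastroke run --seed 1 --out study/
achastroke classify --maps study/maps --atlas study/atlas.tif --out calls.csv
```

## Layout

- `src/achastroke/geometry.py` — parametric coronal territory atlas
- `src/achastroke/synthetic.py` — cohort / CBV-map / histology generator
- `src/achastroke/classification.py` — thresholding and the AChAo call
- `src/achastroke/volumetry.py` — edema-corrected volumes, probability maps
- `src/achastroke/stats.py` — the inference chain
- `src/achastroke/pipeline.py`, `cli.py` — orchestration and the CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
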