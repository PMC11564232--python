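# uterovasc

Quantitative analysis of first-trimester utero-placental vascular development
from 3D power-Doppler ultrasound, and its association with maternal serum
angiogenic biomarkers.

Healthy placentation depends on adequate remodelling of the maternal spiral
arteries in the first trimester; aberrant utero-placental vascular development
precedes placenta-related complications such as preeclampsia, fetal growth
restriction and preterm birth. This package implements two voxel-based imaging
markers of that development and the longitudinal statistics used to relate
them to circulating angiogenic factors:

- **uPVV** (utero-placental vascular volume, cm³): the thresholded
  power-Doppler voxels inside the placental segment, summed as voxel volume —
  a measure of *volumetric* vascular development.
- **uPVS** (utero-placental vascular skeleton): the one-voxel-wide centerline
  network obtained by iteratively peeling the uPVV, with every skeleton voxel
  classified by its number of 26-adjacent skeleton voxels (1 → end point,
  2 → vessel point, 3 → bifurcation point, ≥ 4 → crossing point) — a measure
  of *morphologic (branching)* development. Derived characteristics: total
  vascular length (skeleton voxel count × voxel edge length, mm), average
  vascular thickness (mean number of peeled voxel layers × voxel edge length,
  mm), and branching densities (end/bifurcation/crossing points per cm³ of
  uPVV).

Together with the placental volume (PV) these form eleven markers per scan.
Marker trajectories over gestational age (GA) are analysed on transformed
scales (cube root for volumes, square root for counts/lengths/thickness,
natural log for densities and for most serum biomarkers) with linear mixed
models,

```
t(marker)_ij = b0 + b1·gc_ij + b2·gc_ij² + β·t(biomarker)_i + covariates + u_i + e_ij
```

where `gc` is GA centred at 9 weeks, `u_i` a subject random intercept, and β
the association of interest between an 11-week serum biomarker (PlGF, sFlt-1,
sEng, sFlt-1/PlGF, sEng/PlGF) and the marker trajectory. Model 1 adjusts for
GA only; model 2 additionally adjusts for maternal age, BMI, parity,
conception mode, fetal sex, smoking, alcohol and folic acid use.

Because patient imaging and serum data are not redistributable, the package
ships two synthetic-data generators that are first-class, tested components:

- `synth_vasculature` grows branching tube trees in continuous millimetre
  space with known tip/bifurcation/crossing counts, centerline length and
  radii, and rasterizes them into Doppler-like voxel volumes — ground truth
  for every imaging operation.
- `synth_cohort` simulates longitudinal cohorts (default 185 subjects, visits
  at 7/9/11 weeks) with quadratic GA trajectories, serum biomarkers coupled to
  markers on the analysis scales, realistic covariates, and
  placenta-related-complication labels assigned by the standard obstetric
  definitions — ground truth for the statistical stage.

## Worked example

Generate a Y-shaped phantom (one bifurcation), rasterize it, and run the
marker pipeline:

```bash
uterovasc phantom --generations 1 --seed 7 --outdir out/ph
uterovasc markers --grid out/ph/grid.nii.gz --mask out/ph/mask.nii.gz \
    --threshold 0 --outdir out/mk
cat out/mk/markers.csv
```

```
pv_cm3,upvv_cm3,end_points,bifurcation_points,crossing_points,vessel_points,total_length_mm,avg_thickness_mm,density_end,density_bifurcation,density_crossing
6.975,0.156625,3,1,0,67,35.5,1.0,19.154030327214688,6.384676775738229,0.0
```

The skeleton recovers the tree's topology exactly: 3 end points (two leaf
tips plus the trunk origin) and 1 bifurcation. Total length 35.5 mm
underestimates the 40 mm continuous centerline because the voxel-count rule
counts diagonal steps as one voxel length (a documented bias of the literal
definition); average thickness 1.0 mm ≈ the mean tube radius.

Simulate a cohort in which ln PlGF shifts the cube-root uPVV trajectory by a
true coefficient of 0.39, then check that the adjusted mixed model recovers
it:

```bash
uterovasc recover --biomarker plgf --marker upvv_cm3 --beta 0.39 \
    --n-replicates 200 --seed 11 --outdir out/rec
```

```
recovered beta 0.3942 (injected 0.39, bias +0.0042, coverage 0.94) -> out/rec
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline parameter-recovery results
from scratch: for each of four published adjusted ln(PlGF) coefficients
(on cube-root uPVV, square-root total vascular length, cube-root PV and
square-root bifurcation points), it generates 200 replicate cohorts of 185
subjects with that coefficient injected as simulation truth, refits the
adjusted mixed model per replicate, and reports the mean recovered
coefficient:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model assumptions, the synthetic-data stated
world, numerical choices and known limitations.
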