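# lungdce

Quantification of lung perfusion from dynamic contrast-enhanced (DCE)
thoracic MRI, built for follow-up studies of children after congenital
diaphragmatic hernia (CDH) repair — and for anyone who needs voxelwise
pulmonary perfusion maps, per-lung-side summaries and the cohort
statistics that go with them.

After CDH repair the lung on the hernia side (ipsilateral) is hypoplastic;
perfusion MRI can grade that deficit without ionizing radiation. This
package implements the full analysis chain:

1. **Kinetics** — convert the 4D signal S(x, t) to indicator concentration
   by baseline subtraction, extract the arterial input function (AIF) from
   a pulmonary-trunk ROI, and deconvolve each voxel's tissue curve. The
   indicator-dilution model is

   C_t(t) = f · (C_a ⊛ R)(t),

   discretized as a lower-triangular Toeplitz system A·fr = c with
   A[i,j] = Δt·C_a(t_{i−j}) and inverted by **truncated SVD** (singular
   values below a fraction of σ_max are zeroed; default 15%). Readouts:
   PBF = 6000·max fr (mL/100 mL/min), PBV = 100·∫C_t/∫C_a (mL/100 mL),
   MTT = 60·PBV/PBF (s, central volume theorem).
2. **ROI analysis** — hilar macrovessel exclusion (explicit mask or a PBV
   percentile cut), unweighted per-side means, lung volumes from voxel
   counts, and the per-subject ipsilateral/contralateral PBF ratio.
3. **Cohort statistics** — paired and unpaired (Welch/Student) t-tests,
   Pearson correlation, Shapiro–Wilk, spirometric impairment typing
   (obstructive iff FEV1/FVC < 0.70, restrictive iff FVC < 80% predicted),
   and report tables comparing sides, groups and ECMO/respiratory-disorder
   subgroups.
4. **Synthetic data** — digital thorax phantoms (two lung ellipsoids,
   trunk ROI, hilar vessels), a gamma-variate bolus, forward-model
   rendering at 1.5 s / 2 mm / 5 baseline frames, and whole-cohort
   generators with known ground truth calibrated to published group
   statistics, so every stage is testable without patient data.

## Worked example

```python
import lungdce as L

phantom = L.make_phantom((32, 32, 32), affected_side="left", seed=1)
truth = L.KineticGroundTruth.from_side_values(
    phantom, pbf={"left": 60.4, "right": 90.0}, mtt={"left": 6.3, "right": 6.0}
)
series = L.render_dce(phantom, truth, L.AcquisitionConfig(noise_sigma=1.0, seed=1))

model = L.PerfusionModel(
    series,
    trunk_mask=phantom.trunk_mask,
    left_mask=phantom.left_lung_mask,
    right_mask=phantom.right_lung_mask,
    vessel_mask=phantom.vessel_mask,
    subject_id="CDH-001", hernia_side="left",
)
result = model.fit()
print(result.summary())
```

```
Perfusion results — subject CDH-001 (CDH)
==========================================================
parameter                    ipsilateral   contralateral
PBF (mL/100 mL/min)                67.94           92.29
PBV (mL/100 mL)                     7.44           10.21
MTT (s)                             6.62            6.66
Lung volume (mL)                   13.24           14.40
PBF ratio (ipsi/contra)            0.736
AIF ROI: 49 voxels; TSVD truncation: 15%; excluded voxels: 52
```

The left (ipsilateral) lung was rendered with ground-truth PBF
60.4 mL/100 mL/min against 90.0 contralaterally; at this noise level the
fitted side means recover the flow deficit (ratio 0.736, true 0.67), the
PBV/MTT values carry the expected coarse-frame-spacing bias discussed in
`docs/methods.md`, and 52 noisy voxels were excluded as invalid. The small
lung volumes simply reflect the 32³ toy grid.

Cohort level, statsmodels-style:

```python
cohort = L.generate_cohort(L.cdh_cohort_spec(54, seed=1))
report = L.CohortModel(cohort.subjects, cohort.spirometry).fit()
print(report.summary())          # side/group/subgroup tables + correlations
report.tests["paired:pbf"].p_value   # 1.2e-10
```

## Command line

```bash
lungdce simulate --out out/ --seed 1 --render
lungdce quantify --series s.nii.gz --aif-mask trunk.nii.gz \
    --lung-mask left.nii.gz --lung-mask right.nii.gz --threshold 0.15 --out maps/
lungdce roistats --maps maps/ --masks masks/ --meta meta.csv --out subjects.csv
lungdce cohort --subjects subjects.csv --spiro spiro.csv --out report/
lungdce run-all --out study/ --seed 1
```

All image I/O is NIfTI (.nii.gz); tables are UTF-8 CSV; reports are
written as CSV and JSON. Everything is deterministic under a fixed seed.

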