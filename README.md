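# rvquant

Spatial comparison of paired end-diastolic ventricular segmentations from 3D
echocardiography and cardiac magnetic resonance (CMR), aimed at the globular
*systemic right ventricle* of patients with hypoplastic left heart syndrome
(HLHS). Echo is known to report smaller end-diastolic volumes (EDV) than CMR;
this package quantifies **where** on the ventricle that difference lives.

It is written for researchers with paired binary segmentation masks (NIfTI or
MetaImage) and six named anatomical landmarks per image. Because such patient
data are rarely shareable, a synthetic phantom generator with full ground
truth is a first-class part of the package and drives every test.

## What it computes

1. **Landmark-based rigid alignment.** Six landmarks per modality — the
   atrioventricular valve center (1), the inferior (2), anterior (3), left
   (4), and right (5) annulus points, and the apex (6) — give the closed-form
   least-squares rigid transform (SVD of the cross-covariance matrix with a
   determinant sign fix, so a reflection is never returned). The echo mask is
   resampled into CMR space with nearest-neighbor interpolation.
2. **14-segment parcellation.** The landmark frame (long axis apex→valve,
   in-plane reference anterior→inferior) divides the ventricle into four
   layers along the normalized height h — apical [0, 0.25), medial
   [0.25, 0.5), basal [0.5, 0.75), valvular [0.75, 1] — holding 1, 4, 6, and
   3 angular sectors. The valvular half-ring covers only the free-wall
   semicircle; septal voxels at valvular height extend the basal septal
   sectors upward.
3. **Consensus and volume-difference statistics.** Expert masks are combined
   voxelwise by a strict majority (mean > 0.5). Globally,
   ΔEDV = EDV_echo − EDV_CMR (ml); regionally, for every region r,

   ΔEDV_r = (EDV_r,echo − EDV_r,CMR) / EDV_CMR,

   reported in percent of the *total* CMR volume, so the 14 fractions sum to
   the global relative difference. Cohort output is per-region mean ± SD
   across patients, as bulls-eye plots, bar charts, and CSV tables.

## Worked example

Generate a 5-patient synthetic cohort (CMR volumes 18–58 ml, 3 experts per
image, a 14.2% apical echo deficit, a 5% uniform medial deficit, and a random
rigid echo/CMR misalignment), then run the full analysis:

```sh
rvquant simulate --out cohort --n-patients 5 --seed 7
rvquant analyze --dataset cohort --out results
```

`results/global_volumes.txt` from this exact run:

```
Patient    Echo          CMR           Echo-CMR
---------  ------------  ------------  ------------
patient_1  27.02 ± 0.08  33.56 ± 0.10  -6.54 ± 0.18
patient_2  33.46 ± 0.12  41.44 ± 0.09  -7.98 ± 0.20
patient_3  17.79 ± 0.02  22.03 ± 0.04  -4.25 ± 0.06
patient_4  41.68 ± 0.11  51.45 ± 0.04  -9.77 ± 0.15
patient_5  21.26 ± 0.09  26.24 ± 0.08  -4.98 ± 0.14

End-diastolic volumes in millilitres, mean ± SD over experts.
```

Echo underestimates CMR for every phantom, as designed. The cohort regional
means (`results/cohort_summary.csv`) localize the loss: the apical segment 14
recovers **−14.2%**, each of the four medial segments ≈ **−1.2 to −1.4%**
(summing to the planned −5%), and the basal/valvular segments stay at 0.0%
— i.e. the pipeline recovers the ground-truth spatial pattern through
consensus, registration, resampling, and parcellation. Landmark residuals are
~1e-14 mm here because the synthetic landmarks correspond exactly; on real
data residuals of a few mm are expected. Per-patient bulls-eye plots,
short-axis contour overlays (4 planes), transforms, and a provenance record
land in `results/`.

The same steps are available as library calls (`rvquant.synthetic.make_cohort`,
`rvquant.pipeline.analyze_dataset`) — see `docs/methods.md` for the model
details and conventions.

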