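# cardioreorient

Fully automatic reorientation and quantification of 3-D cardiac PET
myocardial-metabolism volumes.

Clinical reading of cardiac FDG-PET requires short-axis (SA) slices —
planes perpendicular to the left-ventricular (LV) long axis — but
reconstructed volumes come out in the scanner's transaxial frame, tilted by
an oblique, patient-specific angle. Manual realignment is slow and poorly
reproducible. This package implements an automatic pipeline for nuclear
medicine researchers and imaging scientists:

1. **Region division (LVG-CED):** canny edge detection with LV position,
   size, circularity and contrast priors, refined by an active contour,
   isolating the heart and resampling it to a unified 80×80×64 grid.
2. **Myocardial segmentation:** unsupervised intensity clustering —
   K-means, fuzzy c-means (FCM), and their particle-swarm-optimized
   variants (PSO-FCM is the default) — or maximum radioactivity sampling.
3. **Ellipsoid fitting:** the myocardial point cloud is fitted by the
   10-parameter quadric
   `a1x² + a2y² + a3z² + a4xy + a5xz + a6yz + a7x + a8y + a9z + a10 = 0`
   by linear least squares (`a10 = −1`) or by SVD (unit-norm null vector).
   The LV long axis is the major principal axis of the quadratic form; the
   deflection angles α (about x) and β (about y) factor it as
   `u = H2(β)·H1(α)·e_z`.
4. **Reorientation:** affine resampling through `R = H2·H1` about the LV
   centroid produces the SA stack plus HLA/VLA views.
5. **Quantification:** hemisphere-plus-cylinder sampling into a 576-sector
   polar map, reduced to the AHA 17-segment bullseye and the LAD/RCA/LCX
   territories, with the per-segment similarity
   `m = |1 − (p_r − p_o)/p_o|·100%` against a reference map and the summed
   metabolism score (SMS > 2 flags a defect).

Because no clinical dataset ships with the package, a synthetic phantom
module generates FDG-like volumes — truncated ellipsoidal shells at known
orientations with optional wedge defects, right-ventricular uptake, 5 mm
PSF blur and Poisson noise — so the whole chain is validated by parameter
recovery against exact ground truth. See `docs/methods.md` for the model
details and assumptions.

## Worked example

Generate a phantom with a metabolic defect, tilted by α = 12°, β = −8°, and
run the full pipeline on it:

```sh
$ cardioreorient phantom --class defect --alpha 12 --beta -8 --seed 7 --out mmi.nii.gz
wrote mmi.nii.gz (alpha=12.0, beta=-8.0, class=defect)

$ cardioreorient run --in mmi.nii.gz --out case/
{"case_id": "mmi.nii.gz", "success": true,
 "alpha_pred": 12.005327676953856, "beta_pred": -7.888317999154121, ...}
```

The pipeline recovered the deflection angles to 0.005° and 0.11° despite
the defect, the blur and the count noise; `case/` holds the SA volume
(`sa.nii.gz`) and the 17 AHA segment values (`seg17.csv`). The same stages
are available individually (`divide`, `segment`, `fit`, `reorient`,
`polarmap`), and `cardioreorient batch` runs a whole phantom study and
prints the per-class Pearson/Kendall/Spearman agreement table between
predicted and true angles.

From Python:

```python
from cardioreorient import (PhantomSpec, generate_phantom, run_pipeline,
                            PipelineConfig)

vol, truth = generate_phantom(PhantomSpec(alpha_true=12.0, beta_true=-8.0, seed=7))
case = run_pipeline(vol, PipelineConfig(seed=1))
print(case.alpha_pred, case.beta_pred)   # ~12.0, ~-8.0
print(case.polar.seg17)                  # 17 AHA segment values
```

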