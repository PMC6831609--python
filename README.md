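# iodoperf

Quantitative iodine-density CT myocardial perfusion analysis.

Dynamic dual-energy CT can image the first pass of an iodine contrast
bolus through the thorax as a series of *quantitative iodine-density maps*
(mg/ml), free of the beam-hardening and soft-tissue offsets that plague
Hounsfield-based perfusion analysis. `iodoperf` turns such a dynamic
series into absolute hemodynamic maps of the myocardium and surrounding
structures, and ships a fully synthetic, analytically calibrated thorax
phantom so every stage can be validated without scan data. It is intended
for researchers developing or evaluating quantitative CT perfusion
protocols.

## Model

Each pixel's time–enhancement curve I(t) (iodine density vs acquisition
time) is modelled as a baseline-shifted gamma-variate bolus:

```
I(t) = I0 + A (t - t0)^alpha exp(-(t - t0) / beta),   t > t0
```

fitted in two steps: a first fit of all retained samples locates a
preliminary peak, and a second fit discards samples more than 12 s past
that peak, excluding the recirculated second bolus transit. From the
fitted parameters the maximal-slope method gives four maps in closed form:

| Quantity | Definition | Units |
|---|---|---|
| peak enhancement | Imax − Imin = A(αβ)^α e^(−α) | mg/ml |
| perfusion | max_t dI/dt, at t0 + β(α − √α) | mg/ml/s |
| time to peak | t(Imax) − reference | s |
| iodine volume | ∫ I(t) dt over [0, 50 s], truncated where I(t) < 0.25 mg/ml post-peak | mg/ml·s |

Pixels whose density never reaches 0.55 mg/ml, or whose fit fails, are
masked invalid; maps are median-filtered with a 3×3 kernel. A semi-static
*two-shot* estimator approximates the peak-enhancement map from just two
saturation-phase frames (≈23–25 s), trading an ~7× dose reduction
(135 mGy → 18 mGy at 9 mGy per frame) for a 5–15 % myocardial error and
a deliberate underestimation of fast, early-peaking blood-pool structures.

## Worked example

Render the noise-free reference phantom on a 64×64 grid, fit every pixel,
derive the maps and summarise per region:

```python
from iodoperf import (default_phantom, render_series, fit_field,
                      compute_maps, smooth_maps, roi_statistics)

spec = default_phantom(shape=(64, 64), noise_sigma=0.0)
render = render_series(spec)
maps = smooth_maps(compute_maps(fit_field(render.series)))
report = roi_statistics(maps, render.region_masks, reference="descending_aorta")
print(report[["peak_enhancement_median", "perfusion_median",
              "time_to_peak_median", "volume_median",
              "peak_enhancement_ratio_pct"]].round(3).to_string())
```

prints

```
                  peak_enhancement_median  perfusion_median  time_to_peak_median  volume_median  peak_enhancement_ratio_pct
region
myocardium                           0.92             0.085               18.655          29.89                      11.856
left_ventricle                       7.52             1.269               12.390          96.77                      96.907
right_ventricle                      3.77             1.560                6.720          62.73                      48.582
descending_aorta                     7.76             1.232               14.182          98.19                     100.000
ventral_lung                         1.01             0.190                9.264          17.26                      13.015
pulmonary_artery                     6.92             1.250                9.830          95.93                      89.175
```

The myocardium enhances by 0.92 mg/ml (11.86 % of the descending aorta),
perfuses at 0.085 mg/ml/s and accumulates an iodine volume of
29.89 mg/ml·s — the pipeline recovers the phantom's calibrated in-vivo
reference values exactly on noise-free data. Time-to-peak is reported on
the acquisition clock (the myocardium peaks ≈18.7 s after scan start,
4–6 s after the great vessels).

The same pipeline is scriptable from the shell:

```bash
iodoperf simulate --out run --grid 128
iodoperf fit --series run/series.nii.gz --out run/fits.npz
iodoperf maps --fits run/fits.npz --out run/maps \
    --rois run/regions.txt --roi-names run/regions.json \
    --reference-region descending_aorta
iodoperf twoshot --series run/series.nii.gz --offset-map run/baseline.txt --out run/twoshot
```

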