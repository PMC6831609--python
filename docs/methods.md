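# Methods

## The measurement being modelled

A dynamic dual-energy CT perfusion study records a single transverse
thorax slice repeatedly while an iodine bolus transits the heart. The
spectral reconstruction yields, per frame, a quantitative iodine-density
image in mg/ml. The protocol emulated throughout this package is a
rest-state porcine acquisition: 36 ECG-triggered frames within 26 s,
0.40 × 0.40 mm² pixels, 9 mGy CTDIvol per frame, 40 ml of a 300 mg/ml
iodine agent. Frames with pronounced cardiac/thoracic motion are
rejected, leaving 15 non-equidistantly spaced samples per pixel.

## Curve model and fitting

Each pixel's time–enhancement curve is modelled as a gamma-variate bolus
plus a constant baseline:

    I(t) = I0 + A (t − t0)^α exp(−(t − t0)/β),  t > t0.

The classical bolus model has no offset; the baseline term is included
because myocardial tissue shows a small non-zero pre-contrast
iodine-density reading (0.16 mg/ml in the emulated study) and peak
enhancement is defined as Imax − Imin. I0 is initialised from the mean
of the samples preceding contrast arrival (first sample exceeding the
minimum by 3× a robust noise scale estimated from successive
differences) and then refined jointly in the fit.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trf, tolerances 1e-10) with a deterministic start: t0 from the last
sub-threshold sample, α and β from a log-linearisation of log(I − I0) on
the rising limb, A from the observed maximum. Bounds (A ≤ 100 mg/ml/s^α,
α ∈ (0.1, 20], β ∈ (0.05, 60] s, t0 ∈ [0, t_max]) are numerical guards,
not physiology, and are exposed in configuration. A fit that lands on a
bound of A, α or β — or on the upper t0 bound — is flagged unconverged;
t0 = 0 is a legitimate interior value (fast central structures enhance
from the first frame). Flat curves short-circuit to unconverged without
raising, so whole-image sweeps never abort.

**Recirculation handling.** The second (recirculated) bolus transit
biases late samples upward. The two-step procedure fits all samples,
takes the preliminary peak time t0 + αβ, then refits on samples no later
than 12 s past it. If the exclusion leaves fewer than 5 samples the
step-1 fit is kept and flagged (`used_fallback`), avoiding holes in maps.

## Map derivation (maximal-slope method)

Per converged pixel, in closed form:

* peak enhancement = A(αβ)^α e^(−α) (peak density minus baseline);
* perfusion = max dI/dt = A·[β(α−√α)]^(α−1) e^(−(α−√α)) √α for α > 1.
  For α ≤ 1 the analytic slope is unbounded at t0+; those (rare,
  noise-driven) pixels get a bounded grid-search maximum over the
  acquisition window and a degenerate flag, keeping maps finite;
* time to peak = t0 + αβ on the acquisition clock (default
  `ttp_reference="scan_start"`), or αβ past bolus arrival with
  `"bolus_arrival"`. Both readings of the t(Imin) reference are
  defensible; the switch makes the choice explicit;
* iodine volume = ∫ I(t)dt − I0·t over [0, t_end], computed via the lower
  incomplete gamma function, with t_end the earlier of 50 s and the first
  post-peak time the *total* fitted density (baseline included) drops
  below 0.25 mg/ml. The threshold is applied to the total density because
  the measured iodine density — offset and all — is what the washout
  criterion refers to; for the myocardium (slow washout, 0.16 mg/ml
  offset) the stop never fires inside the window.

A pixel is valid when its fit converged and baseline + peak enhancement
reaches 0.55 mg/ml; invalid pixels are NaN (rendered black). The four
maps are smoothed by a 3×3 median filter that excludes invalid pixels
from every neighbourhood and never extends the valid mask.

## Two-shot estimator

Peak enhancement alone can be estimated without dynamics: average two
frames from the myocardial saturation phase (23.3 s and 24.9 s here),
apply a mild Gaussian blur (σ = 1 px by default — the smallest smoothing
that visibly suppresses single-pixel noise, standing in for the
smoothing effect of the fitting routine), subtract a pre-contrast offset
(scalar literature value, scout frame, or per-pixel map), clip at zero.
Structures that peak early and wash out fast (ventricles, aorta,
pulmonary artery) are underestimated several-fold by construction; the
saturated myocardium is recovered to within roughly 5–15 %.

## The digital phantom

`default_phantom()` builds a 2-D single-slice thorax: a myocardial
annulus around a left-ventricular disk, right ventricle, descending
aorta, pulmonary artery and a ventral lung field, disjoint by
construction, scaled to any grid (default 256×256).

**Calibration.** Each region's kinetics are obtained by inverting the
map equations: the slope/peak ratio fixes β given α, the peak fixes A,
and a 1-D Brent root-find in α matches the iodine-volume target to
better than 1e-6 relative; t0 = max(0, t_hint − αβ) places the peak at
the requested time when feasible. Targets are the reference in-vivo
values (myocardium 0.92 mg/ml, 0.085 mg/ml/s, 29.89 mg/ml·s, …), using
the same stop-criterion volume definition as the map generator so that
generator, truth and analysis agree. Infeasible target combinations
raise a calibration error naming the violated constraint. One constraint
is structural: for the myocardial targets the ratios pin αβ ≈ 18.7 s
regardless of α, so no non-negative t0 can place the peak at the 17.12 s
hint; the phantom's myocardial ground-truth time-to-peak is therefore
the analytic ≈18.7 s (consistent with a t(Imin) reference at the first
retained frame rather than t = 0).

**Sampling.** The default frame clock is uniform at 26/36 s with the
four grid points nearest 7.5, 10.9, 23.3 and 24.9 s snapped onto those
landmark times (snap < half-spacing, so monotonicity is preserved); 15
retained indices cover one pre-contrast frame, the upslope densely, and
two saturation-phase frames.

**Recirculation.** Modelled as a delayed, scaled copy of the first pass
(scale 0.2), whose *onset* trails the first-pass peak by 15 s — i.e.
beyond the 12-s exclusion window, so a correct two-step fit sees only
clean first-pass samples while a single-step fit is visibly biased.

**Noise.** I.i.d. additive Gaussian noise, σ = 0.05 mg/ml by default
(the magnitude of per-ROI standard deviations on iodine maps at this
dose), seeded and bit-reproducible.

What the phantom does *not* emulate: cardiac/respiratory motion,
partial-volume and beam-hardening physics, spatially correlated
reconstruction noise, heterogeneous intra-region kinetics, 3-D geometry.
Passing recovery tests therefore demonstrates the correctness of the
fitting and map arithmetic under the stated acquisition and noise
conditions, not robustness to motion or spectral-decomposition error.

## Problem sizes and numerical choices

Recovery tests and the acceptance script run the pixel-wise fit on a
64×64 grid (≈600 in-region fits, seconds of CPU) — region medians are
grid-independent because regions are kinetically homogeneous. The
two-shot error study runs at the native 256×256 grid, where the 1-px
blur is genuinely "minor" relative to the ≈16-px-wide myocardial
annulus; on very coarse grids the blur's partial-volume mixing, not the
estimator, dominates the error. 200 replicates give a stable median
(spread ≈ ±0.2 percentage points).

Ties and degenerate inputs: fractional ROI pixel counts round
half-to-even (50 mm² at 0.40 mm → 312 pixels); reported dose/load
figures round half away from zero to integers while exact values are
retained; empty ROIs, mismatched sidecars, non-monotonic clocks and
non-iodine units are rejected with named errors rather than guessed at.

## Known limitations

* The gamma-variate is a descriptive bolus model; no arterial-input
  deconvolution, hematocrit or blood-volume scaling is applied — maps
  are absolute iodine quantities, not ml/100 g/min physiology.
* Time-to-peak depends on the chosen reference convention (see switch).
* The two-shot estimator assumes the saturation-phase timing is known;
  mistimed frames degrade it in ways the phantom does not model.
* Only 2-D single-slice series are handled; multi-slice/4-D data must be
  processed slice by slice.
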