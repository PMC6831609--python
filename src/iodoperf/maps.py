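"""Pixel-wise fitting and quantitative perfusion-map generation.

Every pixel of a dynamic iodine-density series is fitted independently
with the two-step gamma-variate routine; from the fitted parameters four
co-registered quantitative maps are derived with the maximal-slope method:

* peak enhancement  Imax - Imin                     [mg/ml]
* perfusion         max_t dI/dt                     [mg/ml/s]
* time to peak      t(Imax) - reference time        [s]
* iodine volume     integral of I(t) over the       [mg/ml*s]
                    washout-limited window

Pixels whose fit failed, or whose density never reaches the validity floor
(default 0.55 mg/ml), are flagged invalid and carry NaN; maps are smoothed
with a validity-aware 3x3 median filter to suppress pixel-wise fit noise.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FitInputError
from .tec import (
    FitBounds,
    FitResult,
    GammaVariateParams,
    TimeEnhancementCurve,
    fit_first_pass,
    gv_max_slope,
    truncated_volume,
)

__all__ = [
    "DynamicSeries",
    "FitField",
    "PerfusionMaps",
    "QUANTITIES",
    "fit_field",
    "compute_maps",
    "smooth_maps",
    "roi_statistics",
    "roi_mean_curve",
]

logger = logging.getLogger(__name__)

QUANTITIES = ("peak_enhancement", "perfusion", "time_to_peak", "volume")


@dataclasses.dataclass(frozen=True)
class DynamicSeries:
    """A dynamic iodine-density frame stack with acquisition timestamps.

    ``frames`` is (time, rows, cols) in mg/ml; ``frame_times`` are the
    acquisition times in seconds (strictly increasing, possibly
    non-equidistant); ``pixel_spacing`` is the in-plane pixel size in mm.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float = 0.40
    units: str = "mg/ml"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "frame_times", t)
        if f.ndim != 3:
            raise FitInputError("frames must be a 3-D (time, rows, cols) array")
        if t.ndim != 1 or t.size != f.shape[0]:
            raise FitInputError("frame_times length must equal the number of frames")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise FitInputError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise FitInputError("frames must be finite")
        if self.pixel_spacing <= 0:
            raise FitInputError("pixel_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def pixel_curve(self, row: int, col: int) -> TimeEnhancementCurve:
        return TimeEnhancementCurve(self.frame_times, self.frames[:, row, col], self.units)


@dataclasses.dataclass(frozen=True)
class FitField:
    """Per-pixel gamma-variate fit results stored as dense parameter planes."""

    amplitude: np.ndarray
    t0: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    baseline: np.ndarray
    r_squared: np.ndarray
    n_points_used: np.ndarray
    preliminary_peak_time: np.ndarray
    converged: np.ndarray
    used_fallback: np.ndarray
    t_max: float  # last acquisition time, used for degenerate-slope searches

    @property
    def shape(self) -> tuple[int, int]:
        return self.converged.shape

    def result_at(self, row: int, col: int) -> FitResult:
        return FitResult(
            GammaVariateParams(
                float(self.amplitude[row, col]),
                float(self.t0[row, col]),
                float(self.alpha[row, col]),
                float(self.beta[row, col]),
                float(self.baseline[row, col]),
            ),
            float(self.r_squared[row, col]),
            int(self.n_points_used[row, col]),
            float(self.preliminary_peak_time[row, col]),
            bool(self.converged[row, col]),
            bool(self.used_fallback[row, col]),
        )


@dataclasses.dataclass(frozen=True)
class PerfusionMaps:
    """The four quantitative maps plus validity mask and per-pixel R^2.

    Invalid pixels (failed fit or sub-threshold enhancement) carry NaN in
    all four maps and are rendered black by the export helpers.
    """

    peak_enhancement: np.ndarray
    perfusion: np.ndarray
    time_to_peak: np.ndarray
    volume: np.ndarray
    valid_mask: np.ndarray
    r_squared: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid_mask.shape

    def __getitem__(self, quantity: str) -> np.ndarray:
        if quantity not in QUANTITIES:
            raise KeyError(quantity)
        return getattr(self, quantity)


def fit_field(
    series: DynamicSeries,
    recirculation_cut: float | None = 12.0,
    *,
    bounds: FitBounds | None = None,
) -> FitField:
    """Apply the two-step first-pass fit independently to every pixel.

    Pixel failures are recorded in the ``converged`` plane, never raised.
    Flat (enhancement-free) pixels short-circuit to an unconverged result.
    """
    if series.frames.shape[0] < 5:
        raise FitInputError("need at least 5 frames for pixel-wise fitting")
    rows, cols = series.shape
    planes = {
        name: np.full((rows, cols), np.nan)
        for name in ("amplitude", "t0", "alpha", "beta", "baseline", "r_squared",
                     "preliminary_peak_time")
    }
    n_used = np.zeros((rows, cols), dtype=int)
    converged = np.zeros((rows, cols), dtype=bool)
    fallback = np.zeros((rows, cols), dtype=bool)

    n_failed = 0
    for r in range(rows):
        for c in range(cols):
            fit = fit_first_pass(series.pixel_curve(r, c), recirculation_cut, bounds=bounds)
            p = fit.params
            planes["amplitude"][r, c] = p.amplitude
            planes["t0"][r, c] = p.t0
            planes["alpha"][r, c] = p.alpha
            planes["beta"][r, c] = p.beta
            planes["baseline"][r, c] = p.baseline
            planes["r_squared"][r, c] = fit.r_squared
            planes["preliminary_peak_time"][r, c] = fit.preliminary_peak_time
            n_used[r, c] = fit.n_points_used
            converged[r, c] = fit.converged
            fallback[r, c] = fit.used_fallback
            n_failed += not fit.converged
    logger.info("fit_field: %d/%d pixels converged (%d failures)",
                converged.sum(), rows * cols, n_failed)
    return FitField(
        planes["amplitude"], planes["t0"], planes["alpha"], planes["beta"],
        planes["baseline"], planes["r_squared"], n_used,
        planes["preliminary_peak_time"], converged, fallback,
        t_max=float(series.frame_times[-1]),
    )


def compute_maps(
    fits: FitField,
    integration_window: float = 50.0,
    density_floor: float = 0.55,
    volume_stop: float | None = 0.25,
    window_end: float | None = None,
    ttp_reference: str = "scan_start",
) -> PerfusionMaps:
    """Derive the four quantitative maps from a fitted parameter field.

    Per converged pixel: peak enhancement is the fitted peak density minus
    the baseline; perfusion is the maximal analytic slope (grid-searched
    over the acquisition window for degenerate ``alpha <= 1`` fits); time
    to peak is the fitted peak time referenced to the scan start
    (``ttp_reference="scan_start"``) or to bolus arrival
    (``"bolus_arrival"``); volume integrates the fitted curve over
    ``[0, integration_window]``, truncated at the first post-peak time the
    fitted density (baseline included) drops below ``volume_stop``.

    A pixel is valid when its fit converged *and* its fitted density
    reaches ``density_floor`` (baseline + peak enhancement) at some point
    of the curve; invalid pixels carry NaN in all four maps.
    """
    if ttp_reference not in ("scan_start", "bolus_arrival"):
        raise ValueError("ttp_reference must be 'scan_start' or 'bolus_arrival'")
    conv = fits.converged
    with np.errstate(invalid="ignore"):
        ab = fits.alpha * fits.beta
        t_peak = fits.t0 + ab
        pe = fits.amplitude * np.exp(fits.alpha * (np.log(ab) - 1.0))
        valid = conv & (fits.baseline + pe >= density_floor)

        perfusion = np.full(fits.shape, np.nan)
        regular = conv & (fits.alpha > 1.0)
        tau = fits.beta * (fits.alpha - np.sqrt(fits.alpha))
        perfusion[regular] = (
            fits.amplitude[regular]
            * np.exp((fits.alpha[regular] - 1.0) * np.log(tau[regular])
                     - tau[regular] / fits.beta[regular])
            * np.sqrt(fits.alpha[regular])
        )

    search_window = window_end if window_end is not None else fits.t_max
    volume = np.full(fits.shape, np.nan)
    for r, c in zip(*np.nonzero(valid)):
        params = fits.result_at(r, c).params
        if not params.alpha > 1.0:  # degenerate slope: bounded grid search
            perfusion[r, c] = gv_max_slope(params, search_window=search_window).slope
        volume[r, c], _ = truncated_volume(params, window=integration_window, stop=volume_stop)

    ttp = t_peak if ttp_reference == "scan_start" else ab
    nanmask = np.where(valid, 1.0, np.nan)
    return PerfusionMaps(
        peak_enhancement=pe * nanmask,
        perfusion=perfusion * nanmask,
        time_to_peak=ttp * nanmask,
        volume=volume * nanmask,
        valid_mask=valid,
        r_squared=fits.r_squared.copy(),
    )


def _masked_median3x3(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """3x3 median over valid in-bounds neighbours; NaN where nothing is valid."""
    padded = np.pad(np.where(valid, values, np.nan), 1, constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
        return np.nanmedian(windows, axis=(2, 3))


def smooth_maps(maps: PerfusionMaps) -> PerfusionMaps:
    """3x3 median filter on each quantitative map to damp pixel-wise fit noise.

    Invalid pixels are excluded from every neighbourhood median and remain
    invalid afterwards (the filter never invents values outside the mask).
    """
    valid = maps.valid_mask
    smoothed = {}
    for q in QUANTITIES:
        sm = _masked_median3x3(maps[q], valid)
        smoothed[q] = np.where(valid, sm, np.nan)
    return PerfusionMaps(
        peak_enhancement=smoothed["peak_enhancement"],
        perfusion=smoothed["perfusion"],
        time_to_peak=smoothed["time_to_peak"],
        volume=smoothed["volume"],
        valid_mask=valid.copy(),
        r_squared=maps.r_squared.copy(),
    )


def roi_mean_curve(series: DynamicSeries, roi: np.ndarray) -> TimeEnhancementCurve:
    """Mean time-enhancement curve over an ROI mask of the series."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.shape:
        raise FitInputError("ROI shape does not match the series grid")
    if not roi.any():
        raise FitInputError("ROI is empty")
    return TimeEnhancementCurve(series.frame_times, series.frames[:, roi].mean(axis=1))


def roi_statistics(
    maps: PerfusionMaps,
    rois: Mapping[str, np.ndarray],
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-ROI summary (mean/median/sd of each map over valid pixels).

    One row per ROI, columns ``<quantity>_<stat>``.  With ``reference`` set
    to one of the ROI names, ``<quantity>_ratio_pct`` columns report each
    ROI's median as a percentage of the reference ROI's median.
    """
    if not rois:
        raise FitInputError("no ROIs given")
    rows = {}
    for name, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != maps.shape:
            raise FitInputError(f"ROI {name!r} shape does not match the maps")
        if not roi.any():
            raise FitInputError(f"ROI {name!r} is empty")
        row = {"n_pixels": int(roi.sum()), "n_valid": int((roi & maps.valid_mask).sum())}
        for q in QUANTITIES:
            vals = maps[q][roi]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row[f"{q}_mean"] = float(np.nanmean(vals))
                row[f"{q}_median"] = float(np.nanmedian(vals))
                row[f"{q}_sd"] = float(np.nanstd(vals))
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    if reference is not None:
        if reference not in df.index:
            raise FitInputError(f"reference ROI {reference!r} not among the ROIs")
        for q in QUANTITIES:
            df[f"{q}_ratio_pct"] = 100.0 * df[f"{q}_median"] / df.loc[reference, f"{q}_median"]
    return df
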