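"""Contrast metrics comparing image channels during iodine uptake.

A dual-layer CT study yields several image channels of the same slice -
conventional Hounsfield units, virtual mono-energetic reconstructions and
the iodine-density map.  Their suitability for depicting myocardial
opacification is ranked by two ROI-level quantities comparing a
pre-contrast sample against a saturation-phase sample of the same channel:

* relative increase in signal   RIS = (S_late - S_early) / S_early
* temporal contrast-to-noise    CNR = (S_late - S_early) / sqrt(sd_late^2 + sd_early^2)

Both are dimensionless and invariant under a common rescaling of the
channel, so channels with different units compare directly.
"""

from __future__ import annotations

import dataclasses
import math

from .exceptions import UndefinedMetricError

__all__ = ["RoiSample", "relative_signal_increase", "signal_enhancement", "temporal_cnr", "roi_pixels"]


@dataclasses.dataclass(frozen=True)
class RoiSample:
    """Mean and spread of one image channel over an ROI at one time point.

    ``mean_signal`` and ``sd`` share the channel's units (HU or mg/ml);
    ``roi_area`` is in mm^2; ``channel`` names the reconstruction, e.g.
    ``"conventional"``, ``"monoE40"`` or ``"iodine_density"``.
    """

    mean_signal: float
    sd: float = 0.0
    roi_area: float = 50.0
    timepoint: float = 0.0
    channel: str = "iodine_density"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.roi_area <= 0:
            raise ValueError("roi_area must be > 0")


def _check_channels(early: RoiSample, late: RoiSample) -> None:
    if early.channel != late.channel:
        raise ValueError(f"channel mismatch: {early.channel!r} vs {late.channel!r}")


def relative_signal_increase(early: RoiSample, late: RoiSample) -> float:
    """RIS between a pre-contrast and a saturation sample (dimensionless).

    A value of 5.75 means the signal rose by 575 %.
    """
    _check_channels(early, late)
    if early.mean_signal == 0:
        raise UndefinedMetricError("RIS undefined for zero pre-contrast signal")
    return (late.mean_signal - early.mean_signal) / early.mean_signal


def signal_enhancement(early: RoiSample, late: RoiSample) -> float:
    """Absolute signal increase S_late - S_early, in the channel's units."""
    _check_channels(early, late)
    return late.mean_signal - early.mean_signal


def temporal_cnr(early: RoiSample, late: RoiSample) -> float:
    """Temporal contrast-to-noise ratio between two time points."""
    _check_channels(early, late)
    denom = math.hypot(early.sd, late.sd)
    if denom == 0:
        raise UndefinedMetricError("CNR undefined when both standard deviations are zero")
    return (late.mean_signal - early.mean_signal) / denom


def roi_pixels(area_mm2: float, pixel_spacing: float) -> int:
    """Number of pixels in an ROI of the given area (round-half-to-even).

    A 50 mm^2 ROI at 0.40 mm pixel spacing covers 312.5 pixels, reported
    as 312.
    """
    if area_mm2 <= 0 or pixel_spacing <= 0:
        raise ValueError("area and pixel spacing must be > 0")
    return int(round(area_mm2 / pixel_spacing**2))


def synthesize_channel(density, gain: float = 1.0, intercept: float = 0.0):
    """Affine stand-in channel from an iodine-density map (test scaffolding).

    The phantom emits iodine density only; conventional/monoE channels for
    exercising the channel-comparison metrics are modelled as affine
    transforms of the density.  This is plumbing for tests and demos, not
    spectral physics.
    """
    import numpy as np

    return gain * np.asarray(density, dtype=float) + intercept
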