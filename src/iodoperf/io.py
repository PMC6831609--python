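"""Series and results I/O: NIfTI / multi-page TIFF stacks with JSON sidecars.

A dynamic series on disk is an image stack (time along the last NIfTI axis
or the TIFF page axis) accompanied by a JSON sidecar ``<stem>.json`` with
the fields ``frame_times_s``, ``pixel_spacing_mm`` and ``units``.  Only
iodine-density input (``units == "mg/ml"``) is accepted: Hounsfield-based
series would need arterial-input normalisation, which this pipeline
deliberately avoids.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import FormatError
from .maps import QUANTITIES, DynamicSeries, PerfusionMaps

__all__ = [
    "read_series",
    "write_series",
    "write_outputs",
    "load_config",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG: dict = {
    "phantom": {
        "grid": [256, 256],
        "noise_sigma": 0.05,
        "seed": 2019,
        "recirculation_scale": 0.2,
        "recirculation_delay": 15.0,
    },
    "fit": {
        "recirculation_cut": 12.0,
    },
    "maps": {
        "integration_window": 50.0,
        "density_floor": 0.55,
        "volume_stop": 0.25,
        "ttp_reference": "scan_start",
    },
    "twoshot": {
        "blur_sigma": 1.0,
        "offset": 0.16,
        "times": [23.3, 24.9],
    },
}


def load_config(path=None) -> dict:
    """DEFAULT_CONFIG with a YAML file's sections merged over it."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_series(path, series: DynamicSeries) -> Path:
    """Write a dynamic series as NIfTI or multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
        img = nib.Nifti1Image(np.moveaxis(series.frames, 0, -1), affine)
        nib.save(img, path)
    elif path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, series.frames.astype(np.float64))
    else:
        raise FormatError(f"unsupported series format: {path.name!r} (use .nii[.gz] or .tif[f])")
    sidecar = {
        "frame_times_s": [float(t) for t in series.frame_times],
        "pixel_spacing_mm": float(series.pixel_spacing),
        "units": series.units,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path) -> DynamicSeries:
    """Read a dynamic iodine-density series (NIfTI or TIFF + JSON sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"series file not found: {path}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    for field in ("frame_times_s", "pixel_spacing_mm", "units"):
        if field not in sidecar:
            raise FormatError(f"sidecar {sidecar_path} is missing field {field!r}")
    units = sidecar["units"]
    if units != "mg/ml":
        raise FormatError(
            f"units {units!r} not supported: this pipeline analyses quantitative "
            "iodine-density series in mg/ml (convert Hounsfield data upstream)"
        )
    if _is_nifti(path):
        data = np.asarray(nib.load(path).get_fdata(), dtype=float)
        if data.ndim != 3:
            raise FormatError(f"expected a 3-D NIfTI (rows, cols, time); got shape {data.shape}")
        frames = np.moveaxis(data, -1, 0)
    else:
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    times = np.asarray(sidecar["frame_times_s"], dtype=float)
    if times.size != frames.shape[0]:
        raise FormatError(
            f"sidecar field 'frame_times_s' has {times.size} entries for "
            f"{frames.shape[0]} frames"
        )
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise FormatError("sidecar field 'frame_times_s' must be strictly increasing")
    try:
        return DynamicSeries(frames, times, float(sidecar["pixel_spacing_mm"]), units)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def _write_plane(path: Path, plane: np.ndarray, pixel_spacing: float, fmt: str) -> Path:
    if fmt == "nifti":
        out = path.with_suffix(".nii.gz")
        affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(plane, dtype=float), affine), out)
    else:
        out = path.with_suffix(".tif")
        tifffile.imwrite(out, np.asarray(plane, dtype=np.float64))
    return out


def write_outputs(
    outdir,
    maps: PerfusionMaps,
    report: pd.DataFrame | None = None,
    *,
    config: dict | None = None,
    seed: int | None = None,
    pixel_spacing: float = 0.40,
    fmt: str = "nifti",
    png: bool = False,
) -> dict[str, Path]:
    """Write the four maps, validity mask, R^2 plane, CSV report and manifest.

    Invalid pixels are NaN in the float images; optional ``png=True`` also
    renders 8-bit previews in which invalid pixels are black.  Returns a
    name -> path mapping of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for q in QUANTITIES:
        written[q] = _write_plane(outdir / q, maps[q], pixel_spacing, fmt)
    written["valid_mask"] = _write_plane(
        outdir / "valid_mask", maps.valid_mask.astype(np.uint8), pixel_spacing, fmt
    )
    written["r_squared"] = _write_plane(outdir / "r_squared", maps.r_squared, pixel_spacing, fmt)
    if png:
        for q in QUANTITIES:
            written[f"{q}_png"] = _render_png(outdir / f"{q}.png", maps[q])
    if report is not None:
        csv_path = outdir / "report.csv"
        report.to_csv(csv_path, float_format="%.6g")
        written["report"] = csv_path
    manifest = {
        "software": "iodoperf",
        "version": _version(),
        "seed": seed,
        "config": config or {},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    written["manifest"] = manifest_path
    return written


def _render_png(path: Path, plane: np.ndarray) -> Path:
    """8-bit grayscale preview; NaN (invalid) pixels render black."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(plane, dtype=float)
    finite = np.isfinite(img)
    vmax = np.nanmax(img) if finite.any() else 1.0
    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    shown = np.ma.masked_invalid(img)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    ax.imshow(shown, cmap=cmap, vmin=0.0, vmax=vmax if vmax > 0 else 1.0)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
    return path


def _version() -> str:
    from . import __version__

    return __version__
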