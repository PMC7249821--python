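"""File I/O and the end-to-end pipeline.

Array data travel in HDF5 (datasets ``/rf``, ``/scan_x``, ``/t`` for RF
data; ``/image``, ``/z``, ``/scan_x``, ``/cf`` and optional ``/ascans`` for
reconstructions), configurations in YAML, calibration tables and metric
reports in JSON.  All floats are stored as 64-bit and HDF5 object-time
tracking is disabled, so identical inputs produce bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import yaml

from . import metrics as _metrics
from .forward import RFData, TimeGrid, simulate_bscan
from .geometry import DetectorArray, load_geometry
from .phantoms import make_preset
from .reconstruct import (
    CalibrationTable,
    ReconImage,
    build_model_matrices,
    preprocess_bscan,
    reconstruct_bscan,
)

__all__ = [
    "UserConfigError",
    "PipelineError",
    "write_rf",
    "read_rf",
    "write_image",
    "read_image",
    "save_map_image",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


class UserConfigError(ValueError):
    """A configuration problem the user can fix (missing file, bad grid)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _h5_create(group, name, data):
    group.create_dataset(name, data=np.asarray(data, dtype=np.float64), track_times=False)


def write_rf(rf: RFData, path) -> Path:
    """Write RF B-scan data to HDF5 (/rf, /scan_x, /t + metadata attrs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        _h5_create(f, "rf", rf.data)
        _h5_create(f, "scan_x", rf.scan_x)
        _h5_create(f, "t", rf.grid.t)
        f.attrs["t_start"] = rf.grid.t_start
        f.attrs["dt"] = rf.grid.dt
        f.attrs["element_names"] = list(rf.element_names)
        for key in ("cs", "geometry", "noise_rms", "seed", "mesh_spacing", "config_hash"):
            if rf.meta.get(key) is not None:
                f.attrs[key] = rf.meta[key]
    return path


def read_rf(path) -> RFData:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RF file not found: {path}")
    with h5py.File(path, "r") as f:
        data = f["rf"][()]
        scan_x = f["scan_x"][()]
        grid = TimeGrid(float(f.attrs["t_start"]), float(f.attrs["dt"]), data.shape[2])
        names = tuple(str(n) for n in f.attrs["element_names"])
        meta = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in f.attrs.items()
            if k not in ("t_start", "dt", "element_names")
        }
    return RFData(data, scan_x, grid, names, meta)


def write_image(img: ReconImage, path) -> Path:
    """Write a reconstruction to HDF5 (/image, /z, /scan_x, /cf [, /ascans])."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        _h5_create(f, "image", img.image)
        _h5_create(f, "z", img.z)
        _h5_create(f, "scan_x", img.scan_x)
        _h5_create(f, "cf", img.cf)
        if img.ascans is not None:
            _h5_create(f, "ascans", img.ascans)
        for key, value in img.meta.items():
            if value is not None:
                f.attrs[key] = value
    return path


def read_image(path) -> ReconImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with h5py.File(path, "r") as f:
        img = ReconImage(
            image=f["image"][()],
            z=f["z"][()],
            scan_x=f["scan_x"][()],
            cf=f["cf"][()],
            ascans=f["ascans"][()] if "ascans" in f else None,
            meta={
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in f.attrs.items()
            },
        )
    return img


def save_map_image(img: ReconImage, path) -> Path:
    """Export the maximum-amplitude projection (over depth) as PNG or TIFF."""
    path = Path(path)
    projection = img.image.max(axis=1, keepdims=True).T
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, projection.astype(np.float32))
    else:
        from matplotlib import image as mpl_image

        scale = projection.max() or 1.0
        mpl_image.imsave(path, projection / scale, cmap="magma", origin="lower")
    return path


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of a phantom → simulate → reconstruct → metrics run."""

    geometry: str
    phantom: dict
    scan: dict  # {start, stop, step} in mm
    time_grid: dict  # {t_start, dt, n_samples}
    z_grid: dict  # {start, stop, step} in mm
    cs: float = 1.5
    noise_rms: float = 0.0
    seed: int = 0
    coherence: bool = True
    mode: str = "envelope"
    preprocess: bool = False
    calibration: str | None = None
    mesh_spacing: float = 0.25
    outputs: dict = field(default_factory=dict)

    def scan_positions(self) -> np.ndarray:
        s = self.scan
        return np.arange(s["start"], s["stop"] + 0.5 * s["step"], s["step"])

    def z_positions(self) -> np.ndarray:
        z = self.z_grid
        return np.arange(z["start"], z["stop"] + 0.5 * z["step"], z["step"])

    def grid(self) -> TimeGrid:
        g = self.time_grid
        return TimeGrid(g["t_start"], g["dt"], int(g["n_samples"]))

    def hash(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise UserConfigError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    try:
        cfg = RunConfig(**doc)
    except TypeError as exc:
        raise UserConfigError(f"invalid config {path}: {exc}") from exc
    return cfg


def _resolve_geometry(cfg: RunConfig) -> DetectorArray:
    try:
        return load_geometry(cfg.geometry)
    except FileNotFoundError as exc:
        raise UserConfigError(str(exc)) from exc


def run_pipeline(config: RunConfig, out_dir=None) -> dict[str, Path]:
    """Execute phantom → simulate → reconstruct → metrics and write artifacts.

    Returns the paths of the written files.  Identical configurations (and
    seeds) produce bit-identical outputs.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir) if out_dir is not None else Path.cwd()
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "rf": out_dir / config.outputs.get("rf", "rf.h5"),
        "image": out_dir / config.outputs.get("image", "image.h5"),
        "report": out_dir / config.outputs.get("report", "report.json"),
    }
    stage = "configuration"
    try:
        array = _resolve_geometry(config)
        phantom_spec = dict(config.phantom)
        calibration = None
        if config.calibration is not None:
            calib_path = Path(config.calibration)
            if not calib_path.exists():
                raise UserConfigError(f"calibration file not found: {calib_path}")
            calibration = CalibrationTable.from_json(calib_path)

        stage = "phantom"
        sources = make_preset(phantom_spec.pop("preset"), **phantom_spec)

        stage = "simulate"
        rf = simulate_bscan(
            array,
            sources,
            config.scan_positions(),
            config.cs,
            config.grid(),
            noise_rms=config.noise_rms,
            seed=config.seed,
            max_point_spacing=config.mesh_spacing,
        )
        rf.meta["config_hash"] = config.hash()
        write_rf(rf, outputs["rf"])

        stage = "reconstruct"
        if config.preprocess:
            rf = preprocess_bscan(rf)
        matrices = build_model_matrices(
            array,
            config.z_positions(),
            config.grid(),
            config.cs,
            max_point_spacing=config.mesh_spacing,
        )
        img = reconstruct_bscan(
            rf,
            matrices,
            calibration,
            coherence=config.coherence,
            mode=config.mode,
        )
        img.meta["config_hash"] = config.hash()
        write_image(img, outputs["image"])

        stage = "metrics"
        report = _image_report(img)
        report["config_hash"] = config.hash()
        report["seed"] = config.seed
        outputs["report"].write_text(json.dumps(report, indent=2, sort_keys=True))
    except UserConfigError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outputs


def _image_report(img: ReconImage) -> dict:
    """Summary metrics of a reconstructed image."""
    flat_idx = np.unravel_index(int(np.argmax(img.image)), img.image.shape)
    j, k = flat_idx
    peak = float(img.image[j, k])
    lateral = img.image[:, k]
    axial = img.image[j, :]
    report = {
        "peak_amplitude": peak,
        "peak_scan_x_mm": float(img.scan_x[j]),
        "peak_depth_mm": float(img.z[k]),
        "cf_at_peak": float(img.cf[j, k]),
    }
    try:
        report["lateral_fwhm_um"] = _metrics.fwhm(img.scan_x, lateral)
        report["axial_fwhm_um"] = _metrics.fwhm(img.z, axial)
    except ValueError:
        pass
    return report
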