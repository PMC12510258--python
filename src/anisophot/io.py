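"""File formats, run manifests and the end-to-end pipeline.

Frames travel as multi-page TIFF with a JSON sidecar (time stamps in ps,
pixel pitch in mm, FOV definition); simulated records as HDF5; curves and
chi^2 surfaces as CSV with units in the column names; configurations,
estimates and manifests as JSON.  Every pipeline run emits exactly one
manifest from which its numeric outputs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .mc import DetectionGrid, SpaceTimeRecord
from .optics import FiberGeometry
from .transient import (DEFAULT_FOV_AREA, MSDSeries, TDRCurve, TransientStack,
                        TransientDiffusionModel, integrate_time_resolved)

logger = logging.getLogger("anisophot")

__all__ = [
    "read_stack", "write_stack",
    "read_record", "write_record",
    "read_tdr_csv", "write_tdr_csv",
    "read_msd_csv", "write_msd_csv",
    "write_json", "read_json",
    "RunManifest", "run_pipeline",
]


def write_stack(stack: TransientStack, tiff_path, sidecar_path) -> None:
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    sidecar = {
        "time_stamps_ps": stack.time_stamps.tolist(),
        "pixel_pitch_mm": stack.pixel_pitch,
        "x0_mm": stack.x0,
        "y0_mm": stack.y0,
        "fov_area_mm2": stack.fov_area,
        "fov_center_mm": list(stack.fov_center),
        "meta": _jsonable(stack.meta),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_stack(tiff_path, sidecar_path) -> TransientStack:
    """Load a frame stack, validating pages against the sidecar.

    Sidecars without an FOV entry get the default circular field of view
    (area 13.2 mm^2) with a logged warning.
    """
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = json.loads(Path(sidecar_path).read_text())
    stamps = np.asarray(sidecar["time_stamps_ps"], dtype=float)
    if len(stamps) != len(frames):
        raise ValueError(
            f"sidecar lists {len(stamps)} time stamps but TIFF has "
            f"{len(frames)} pages")
    if "pixel_pitch_mm" not in sidecar:
        raise ValueError("sidecar is missing pixel_pitch_mm")
    if np.any(stamps < 0):
        raise ValueError("negative time stamps in sidecar")
    if "fov_area_mm2" not in sidecar:
        logger.warning(
            "sidecar has no FOV entry; applying the default circular "
            "field of view of area %.1f mm^2", DEFAULT_FOV_AREA)
    pitch = float(sidecar["pixel_pitch_mm"])
    nx = frames.shape[1]
    return TransientStack(
        frames=frames,
        time_stamps=stamps,
        pixel_pitch=pitch,
        x0=float(sidecar.get("x0_mm", -nx * pitch / 2.0)),
        y0=float(sidecar.get("y0_mm", -frames.shape[2] * pitch / 2.0)),
        fov_area=float(sidecar.get("fov_area_mm2", DEFAULT_FOV_AREA)),
        fov_center=tuple(sidecar.get("fov_center_mm", (0.0, 0.0))),
        meta=sidecar.get("meta", {}),
    )


def write_record(record: SpaceTimeRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=record.intensity, compression="gzip")
        f.create_dataset("x_centers_mm", data=record.x_centers)
        f.create_dataset("y_centers_mm", data=record.y_centers)
        f.create_dataset("time_bin_edges_ps", data=record.grid.time_bin_edges)
        f.attrs["photons_launched"] = record.photons_launched
        f.attrs["v_mm_per_ps"] = record.v
        f.attrs["mu_a_applied_mm^-1"] = record.mu_a_applied
        f.attrs["pixel_pitch_mm"] = record.grid.pixel_pitch
        f.attrs["x0_mm"] = record.grid.x0
        f.attrs["y0_mm"] = record.grid.y0
        f.attrs["accounting"] = json.dumps(record.accounting)
        f.attrs["meta"] = json.dumps(_jsonable(record.meta))


def read_record(path) -> SpaceTimeRecord:
    with h5py.File(path, "r") as f:
        intensity = f["intensity"][()]
        edges = f["time_bin_edges_ps"][()]
        grid = DetectionGrid(
            pixel_pitch=float(f.attrs["pixel_pitch_mm"]),
            nx=intensity.shape[0], ny=intensity.shape[1],
            x0=float(f.attrs["x0_mm"]), y0=float(f.attrs["y0_mm"]),
            time_bin_edges=edges)
        return SpaceTimeRecord(
            intensity=intensity, grid=grid,
            photons_launched=int(f.attrs["photons_launched"]),
            accounting=json.loads(f.attrs["accounting"]),
            v=float(f.attrs["v_mm_per_ps"]),
            mu_a_applied=float(f.attrs["mu_a_applied_mm^-1"]),
            meta=json.loads(f.attrs["meta"]),
        )


def write_tdr_csv(curve: TDRCurve, path) -> None:
    pd.DataFrame({
        "time_ps": curve.times,
        "intensity_counts": curve.intensity,
        "uncertainty_counts": curve.uncertainty,
    }).to_csv(path, index=False)


def read_tdr_csv(path) -> TDRCurve:
    df = pd.read_csv(path)
    return TDRCurve(times=df["time_ps"].to_numpy(),
                    intensity=df["intensity_counts"].to_numpy(),
                    uncertainty=df["uncertainty_counts"].to_numpy())


def write_msd_csv(series: MSDSeries, path) -> None:
    pd.DataFrame({
        "time_ps": series.times,
        "msd_par_mm2": series.msd_par,
        "msd_perp_mm2": series.msd_perp,
        "err_par_mm2": series.err_par,
        "err_perp_mm2": series.err_perp,
        "rotation_deg": np.full_like(series.times, series.rotation),
    }).to_csv(path, index=False)


def read_msd_csv(path) -> MSDSeries:
    df = pd.read_csv(path)
    return MSDSeries(
        times=df["time_ps"].to_numpy(),
        msd_par=df["msd_par_mm2"].to_numpy(),
        msd_perp=df["msd_perp_mm2"].to_numpy(),
        err_par=df["err_par_mm2"].to_numpy(),
        err_perp=df["err_perp_mm2"].to_numpy(),
        rotation=float(df["rotation_deg"].iloc[0]),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class RunManifest:
    """Provenance of one pipeline or CLI stage run."""

    stage: str
    config: dict
    seed: int | None = None
    tensor_model: str | None = None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: float = field(default_factory=_time.time)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.config), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        d = asdict(self)
        d["config_hash"] = self.config_hash
        write_json(d, path)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute synth -> analyze -> fit-msd -> fit-tdr with shared seeds.

    ``config`` keys: ``synth`` (SyntheticSpec-like parameters with mode
    'monte-carlo'), ``analyze`` (t_min, elevation_alpha), ``fit``
    (FitConfig overrides), optional ``skip_inverse``.  Returns the result
    bundle as a dict and writes every artifact plus one manifest.
    """
    from .inverse import AbsorptionInversion, FitConfig, ScatteringInversion
    from .optics import OpticalTensorProperties
    from .synth import SyntheticSpec, generate_mc_stack, generate_tdr_curve

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    synth_cfg = dict(config.get("synth", {}))
    props = OpticalTensorProperties.from_dict(synth_cfg.pop("properties"))
    spec = SyntheticSpec.monte_carlo(props, seed=seed, **synth_cfg)
    stack = generate_mc_stack(spec)
    write_stack(stack, out / "stack.tif", out / "stack.json")

    an = config.get("analyze", {})
    geometry = FiberGeometry(elevation_alpha=an.get("elevation_alpha", 0.0))
    model = TransientDiffusionModel(stack, geometry=geometry,
                                    t_min=an.get("t_min", 10.0))
    results = model.fit()
    write_msd_csv(results.msd, out / "msd.csv")
    write_json(results.to_dict(), out / "diffusion_estimate.json")

    bundle = {"diffusion": results.to_dict()}
    if not config.get("skip_inverse", False):
        fit_over = dict(config.get("fit", {}))
        fit_cfg = FitConfig(seed=seed + 1, **fit_over)
        stage1 = ScatteringInversion(results.msd, fit_cfg).fit()
        write_json(stage1.to_dict(), out / "stage1.json")
        tdr = generate_tdr_curve(spec)
        write_tdr_csv(tdr, out / "tdr.csv")
        stage2 = AbsorptionInversion.from_stage1(tdr, stage1, fit_cfg).fit(
            g_profile=False)
        write_json(stage2.to_dict(), out / "stage2.json")
        bundle.update({"stage1": stage1.to_dict(), "stage2": stage2.to_dict()})

    manifest = RunManifest(stage="pipeline", config=config, seed=seed,
                           tensor_model=synth_cfg.get("tensor_model", "norm"),
                           outputs=[str(p.name) for p in sorted(out.iterdir())])
    manifest.write(out / "manifest.json")
    write_json(bundle, out / "results.json")
    return bundle
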