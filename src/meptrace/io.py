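"""Readers and writers: multi-page TIFF stacks, JSON sidecars, CSV, YAML.

Stacks are stored one channel per file with pages along axis 0; physical
metadata (voxel sizes, depths, truth centroids, injection plans) lives in a
JSON sidecar next to the image file.  CSV output uses '.' decimals, comma
separators, a header row, and units embedded in column names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coverage import CoverageResult
from .neurons import PoolExtent, SpotSet
from .synth.injection import InjectionPlan, InjectionSite


def sidecar_path(stack_path: str | Path) -> Path:
    return Path(stack_path).with_suffix(".json")


def write_stack(path: str | Path, volume: np.ndarray,
                metadata: dict | None = None) -> Path:
    """Write a 3D array as a multi-page TIFF plus an optional JSON sidecar."""
    path = Path(path)
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("stack must be 3D (pages, rows, cols)")
    tifffile.imwrite(path, vol, photometric="minisblack")
    if metadata is not None:
        sidecar_path(path).write_text(json.dumps(metadata, indent=2))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF into a (pages, rows, cols) array.

    Metadata comes from the JSON sidecar when present (empty dict
    otherwise).  Ragged page shapes raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path}: {shapes}")
        vol = tif.asarray()
    if vol.ndim == 2:
        vol = vol[None]
    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return vol, meta


def write_sections(out_dir: str | Path, sections, plan=None) -> dict[str, Path]:
    """Write rendered sections as one multi-page TIFF per channel + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    depths = [s.depth_um for s in sections]
    paths = {}
    for ch in ("tracer", "mep"):
        stack = np.stack([s.channels[ch] for s in sections]).astype(np.float32)
        meta = {
            "channel": ch,
            "depths_um": depths,
            "pixel_size_um": sections[0].pixel_size_um,
            "slab_thickness_um": sections[0].slab_thickness_um,
        }
        if plan is not None:
            meta["injection_plan"] = plan_to_dict(plan)
        paths[ch] = write_stack(out_dir / f"{ch}.tif", stack, meta)
    return paths


def plan_to_dict(plan: InjectionPlan) -> dict:
    return {
        "strategy": plan.strategy,
        "muscle_kind": plan.muscle_kind,
        "total_volume_ul": plan.total_volume_ul,
        "sites": [
            {"position_um": list(s.position_um), "depth_mm": s.depth_mm,
             "volume_nl": s.volume_nl}
            for s in plan.sites
        ],
    }


def plan_from_dict(d: dict) -> InjectionPlan:
    sites = tuple(
        InjectionSite(position_um=tuple(s["position_um"]),
                      depth_mm=s["depth_mm"], volume_nl=s["volume_nl"])
        for s in d["sites"])
    return InjectionPlan(strategy=d["strategy"], muscle_kind=d["muscle_kind"],
                         sites=sites)


def write_plan_yaml(path: str | Path, plan: InjectionPlan) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(plan_to_dict(plan), sort_keys=False))
    return path


def read_plan_yaml(path: str | Path) -> InjectionPlan:
    return plan_from_dict(yaml.safe_load(Path(path).read_text()))


def coverage_to_frame(result: CoverageResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"depth_um": d.depth_um, "mep_pixels": d.mep_pixels,
          "mep_pixels_in_ctb": d.mep_pixels_in_ctb, "coverage": d.coverage}
         for d in result.per_depth])


def write_coverage_csv(path: str | Path, result: CoverageResult) -> Path:
    """Coverage CSV: one row per depth plus a mean_coverage footer row."""
    path = Path(path)
    df = coverage_to_frame(result)
    footer = pd.DataFrame([{"depth_um": "mean_coverage", "mep_pixels": "",
                            "mep_pixels_in_ctb": "",
                            "coverage": result.mean_coverage}])
    pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)
    return path


def spots_to_frame(spots: SpotSet) -> pd.DataFrame:
    c = spots.centroids_um
    return pd.DataFrame({
        "id": np.arange(len(spots)),
        "x_rc_um": c[:, 0] if len(spots) else [],
        "y_ml_um": c[:, 1] if len(spots) else [],
        "z_vd_um": c[:, 2] if len(spots) else [],
        "peak": spots.intensities,
    })


def write_spots_csv(path: str | Path, spots: SpotSet) -> Path:
    path = Path(path)
    spots_to_frame(spots).to_csv(path, index=False)
    return path


def write_spot_summary(path: str | Path, spots: SpotSet,
                       extent: PoolExtent) -> Path:
    """Summary JSON: count, per-axis ranges (μm), extent mode, axis semantics."""
    path = Path(path)
    payload = {
        "count": len(spots),
        "range_rc_um": extent.range_rc_um,
        "range_ml_um": extent.range_ml_um,
        "range_vd_um": extent.range_vd_um,
        "mode": extent.mode,
        "axes": {"0": "rostro-caudal", "1": "medio-lateral",
                 "2": "ventro-dorsal"},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def dataclass_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: dataclass_to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_jsonable(v) for v in obj]
    return obj
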