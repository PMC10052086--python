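"""File formats: 16-bit depth and 8-bit RGB/mask PNGs, intrinsics JSON,
height-map TIFFs, PLY point clouds, trait/evaluation CSVs and YAML configs.

Frame files are named by ISO-8601-style timestamps
(``<stamp>_depth.png`` / ``<stamp>_rgb.png`` / ``<stamp>_mask.png``); for
synthetic batches the stamp is the zero-padded day index.  All CSV outputs
carry a schema version column so readers can reject incompatible files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import FrameRGBD
from .geometry import CameraIntrinsics, HeightMap
from .indicators import SpacingEvaluation, TraitRecord, WeightModel
from .segmentation import SegMask

CSV_SCHEMA_VERSION = "1.0"


class IOFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# intrinsics


def write_intrinsics(cam: CameraIntrinsics, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cam), indent=2) + "\n")


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    data = json.loads(Path(path).read_text())
    return CameraIntrinsics(**data)


# ---------------------------------------------------------------------------
# rasters


def write_depth(depth_mm: np.ndarray, path: str | Path, depth_scale: float = 1.0) -> None:
    """Store depth as 16-bit PNG in ``depth_scale`` mm units."""
    units = np.round(np.asarray(depth_mm, dtype=np.float64) / depth_scale)
    if units.min() < 0 or units.max() > 65535:
        raise IOFormatError("depth out of 16-bit range at this scale")
    iio.imwrite(Path(path), units.astype(np.uint16))


def read_depth(path: str | Path, depth_scale: float = 1.0) -> np.ndarray:
    """Read a 16-bit single-channel depth PNG/TIFF, scaled to mm."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2 or arr.dtype != np.uint16:
        raise IOFormatError(
            f"{path}: depth must be 16-bit single channel, got {arr.dtype} {arr.shape}"
        )
    return arr.astype(np.float64) * depth_scale


def write_rgb(rgb: np.ndarray, path: str | Path) -> None:
    if rgb.dtype != np.uint8 or rgb.ndim != 3 or rgb.shape[2] != 3:
        raise IOFormatError("rgb must be 8-bit 3-channel")
    iio.imwrite(Path(path), rgb)


def read_rgb(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 3 or arr.shape[2] < 3 or arr.dtype != np.uint8:
        raise IOFormatError(f"{path}: expected 8-bit 3-channel image, got {arr.dtype} {arr.shape}")
    return arr[..., :3]


def write_mask(mask: SegMask, path: str | Path) -> None:
    """Store a binary mask as 0/255 single-channel PNG."""
    iio.imwrite(Path(path), np.where(mask.data, 255, 0).astype(np.uint8))


def read_mask(path: str | Path, provenance: str = "external") -> SegMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return SegMask(arr, provenance=provenance)


def frame_stamp(timestamp: int | str) -> str:
    return f"day{int(timestamp):03d}" if isinstance(timestamp, (int, np.integer)) else str(timestamp)


def write_frame(frame: FrameRGBD, directory: str | Path, mask: SegMask | None = None) -> dict:
    """Write one frame's depth/RGB (and optional mask) into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stamp = frame_stamp(frame.timestamp)
    paths = {
        "depth": directory / f"{stamp}_depth.png",
        "rgb": directory / f"{stamp}_rgb.png",
    }
    write_depth(frame.depth_mm, paths["depth"], frame.cam.depth_scale)
    write_rgb(frame.rgb, paths["rgb"])
    if mask is not None:
        paths["mask"] = directory / f"{stamp}_mask.png"
        write_mask(mask, paths["mask"])
    return paths


def read_frame(
    depth_path: str | Path,
    rgb_path: str | Path,
    cam: CameraIntrinsics,
    timestamp: int | str | None = None,
) -> FrameRGBD:
    """Load one RGB-D frame; the timestamp falls back to the filename stamp."""
    depth = read_depth(depth_path, cam.depth_scale)
    rgb = read_rgb(rgb_path)
    if depth.shape != rgb.shape[:2]:
        raise IOFormatError(f"{depth_path} and {rgb_path}: shape mismatch")
    if timestamp is None:
        stem = Path(depth_path).stem.replace("_depth", "")
        timestamp = int(stem[3:]) if stem.startswith("day") and stem[3:].isdigit() else stem
    return FrameRGBD(rgb=rgb, depth_mm=depth, cam=cam, timestamp=timestamp)


def write_height_map(hm: HeightMap, path: str | Path) -> None:
    tifffile.imwrite(Path(path), hm.heights_cm.astype(np.float32))


def write_ply(points_mm: np.ndarray, path: str | Path) -> None:
    """ASCII PLY export of an (N, 3) point cloud in mm."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {pts.shape[0]}\n"
            "property float x\nproperty float y\nproperty float z\nend_header\n"
        )
        np.savetxt(fh, pts, fmt="%.3f")


# ---------------------------------------------------------------------------
# tables and configs


def traits_to_frame(traits: Sequence[TraitRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in traits])
    df.insert(0, "schema_version", CSV_SCHEMA_VERSION)
    return df


def evaluations_to_frame(evals: Sequence[SpacingEvaluation]) -> pd.DataFrame:
    rows = []
    for e in evals:
        d = asdict(e)
        d["verdict"] = e.verdict
        rows.append(d)
    df = pd.DataFrame(rows)
    df.insert(0, "schema_version", CSV_SCHEMA_VERSION)
    return df


def read_versioned_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "schema_version" in df.columns and len(df):
        major = str(df["schema_version"].iloc[0]).split(".")[0]
        if major != CSV_SCHEMA_VERSION.split(".")[0]:
            raise IOFormatError(
                f"{path}: unsupported schema major version {df['schema_version'].iloc[0]}"
            )
    return df


def write_weight_model(model: WeightModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(model), indent=2) + "\n")


def read_weight_model(path: str | Path) -> WeightModel:
    return WeightModel(**json.loads(Path(path).read_text()))


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
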