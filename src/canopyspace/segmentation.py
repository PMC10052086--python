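"""Binary lettuce/background segmentation, coverage and mIoU.

Masks are boolean rasters (True = lettuce).  The built-in segmenter is a
classical excess-green-index threshold; learned segmenters can be plugged
in externally as 0/255 PNG masks.  Coverage is the fraction of the imaged
ground area classified as lettuce, in percent; segmentation quality against
an annotated mask is scored with the mean intersection-over-union of the
lettuce and background classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from skimage.filters import threshold_otsu


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SegMask:
    """Binary lettuce/background raster with a provenance tag."""

    data: np.ndarray  # bool, (rows, cols)
    provenance: str = "external"  # classical | external | ground-truth

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise SegmentationError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1, 255))):
                raise SegmentationError("mask must be binary (0/1 or 0/255)")
            object.__setattr__(self, "data", arr != 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def lettuce_pixels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class CoverageValue:
    """Canopy coverage in percent with the context it was measured in."""

    percent: float
    timestamp: Union[int, str, None] = None
    density: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise SegmentationError(f"coverage {self.percent} outside [0, 100]")


def excess_green(rgb: np.ndarray) -> np.ndarray:
    """Excess-green index 2G − R − B per pixel (int16 on 8-bit input)."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SegmentationError(f"expected a 3-channel image, got shape {arr.shape}")
    arr = arr.astype(np.int16) if arr.dtype == np.uint8 else arr.astype(np.float64)
    return 2 * arr[..., 1] - arr[..., 0] - arr[..., 2]


def exg_segment(rgb: np.ndarray, threshold: float | str = 20) -> SegMask:
    """Threshold the excess-green index into a lettuce mask.

    ``threshold`` is a fixed index value (default 20 on 8-bit channels) or
    the string "otsu" for an automatic bimodal threshold.  A pixel is
    lettuce iff its index strictly exceeds the threshold.
    """
    exg = excess_green(rgb)
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise SegmentationError(f"unknown threshold spec {threshold!r}")
        thr = float(threshold_otsu(exg))
    else:
        thr = float(threshold)
    return SegMask(exg > thr, provenance="classical")


def coverage(
    mask: SegMask | np.ndarray,
    timestamp: Union[int, str, None] = None,
    density: float | None = None,
) -> CoverageValue:
    """Coverage in percent: 100 * lettuce pixels / total pixels."""
    mask = mask if isinstance(mask, SegMask) else SegMask(mask)
    total = mask.data.size
    if total == 0:
        raise SegmentationError("empty raster")
    return CoverageValue(100.0 * mask.lettuce_pixels() / total, timestamp, density)


def miou(pred: SegMask | np.ndarray, gt: SegMask | np.ndarray) -> float:
    """Mean IoU over the lettuce and background classes, in [0, 1].

    A class absent from both masks contributes IoU 1 (0/0 treated as 1),
    so the metric is total and equals 1 iff the masks are identical.
    """
    pred = pred if isinstance(pred, SegMask) else SegMask(pred)
    gt = gt if isinstance(gt, SegMask) else SegMask(gt)
    if pred.shape != gt.shape:
        raise SegmentationError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    total = 0.0
    for cls in (True, False):
        p = pred.data == cls
        g = gt.data == cls
        union = np.logical_or(p, g).sum()
        inter = np.logical_and(p, g).sum()
        total += 1.0 if union == 0 else inter / union
    return total / 2.0
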