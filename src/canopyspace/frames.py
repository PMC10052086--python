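"""The in-memory RGB-D frame container shared by the generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraIntrinsics


@dataclass(frozen=True)
class FrameRGBD:
    """One time-stamped top-down RGB + depth raster pair with intrinsics.

    ``depth_mm`` is depth along the optical axis in millimetres (float,
    already scaled from storage units); 0 marks invalid pixels.
    """

    rgb: np.ndarray  # uint8, (rows, cols, 3)
    depth_mm: np.ndarray  # float64, (rows, cols)
    cam: CameraIntrinsics
    timestamp: int | str = 0

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must be (rows, cols, 3), got {self.rgb.shape}")
        if self.depth_mm.shape != self.rgb.shape[:2]:
            raise ValueError("rgb and depth shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth_mm.shape
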