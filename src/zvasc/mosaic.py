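"""Mosaic acquisition planning and data-rate arithmetic.

The camera field of view (960×960 px ≈ 1.097 mm at 10×) is much smaller
than a growing embryo (3.5–4 mm at 5 dpf), so several overlapping
acquisition volumes are tiled along the sample axis. Given a starting
position, tile positions follow automatically with a fixed overlap
fraction (30% by default, enough for reliable stitching); the tile count
is the smallest that covers the expected sample length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionPlan",
    "AcquisitionSettings",
    "plan_tiles",
    "total_volumes",
    "estimate_data_rate",
]

DEFAULT_OVERLAP = 0.30
#: camera field of view at 10×: 960 px × 1.143 µm/px
DEFAULT_FOV_MM = 1.097


@dataclass
class AcquisitionPlan:
    """Tile positions along the sample axis, in µm."""

    start_position: float
    fov_length: float
    overlap_fraction: float
    expected_sample_length: float
    tile_positions: list[float]
    n_tiles: int

    def to_frame(self) -> pd.DataFrame:
        """Stage-position table consumable by the stitching module."""
        return pd.DataFrame(
            {
                "tile_id": range(self.n_tiles),
                "z_um": 0.0,
                "y_um": 0.0,
                "x_um": self.tile_positions,
            }
        )


@dataclass
class AcquisitionSettings:
    """Acquisition parameters entering the data-rate estimate."""

    n_volumes: int = 75
    n_channels: int = 2
    planes_per_volume: int = 200
    frame_pixels: tuple[int, int] = (960, 960)
    bytes_per_pixel: int = 2  # 16-bit images
    interval_minutes: float = 20.0

    def __post_init__(self) -> None:
        values = (self.n_volumes, self.n_channels, self.planes_per_volume,
                  *self.frame_pixels, self.bytes_per_pixel, self.interval_minutes)
        if any(v <= 0 for v in values):
            raise ValueError("all acquisition settings must be positive")


def plan_tiles(
    sample_length_mm: float,
    fov_mm: float = DEFAULT_FOV_MM,
    overlap_fraction: float = DEFAULT_OVERLAP,
    start_position_mm: float = 0.0,
) -> AcquisitionPlan:
    """Smallest tile set covering the sample with a fixed overlap.

    The step between tiles is ``(1 − overlap) × fov``; the number of
    tiles is ``1 + ceil((sample_length − fov) / step)`` (one tile when
    the sample fits a single field of view), so coverage
    ``fov + (n−1)·step`` always reaches the sample length, with ceil
    semantics keeping ``n`` minimal when coverage is exactly met.
    """
    if sample_length_mm <= 0:
        raise ValueError("sample length must be positive")
    if fov_mm <= 0 or not 0 < overlap_fraction < 1:
        raise ValueError("need fov > 0 and 0 < overlap < 1")
    step = (1.0 - overlap_fraction) * fov_mm
    # tiny negative slack so float noise cannot inflate an exact-coverage count
    n = 1 + math.ceil(max(0.0, sample_length_mm - fov_mm) / step - 1e-9)
    positions_um = [(start_position_mm + i * step) * 1000.0 for i in range(n)]
    return AcquisitionPlan(
        start_position=start_position_mm * 1000.0,
        fov_length=fov_mm * 1000.0,
        overlap_fraction=overlap_fraction,
        expected_sample_length=sample_length_mm * 1000.0,
        tile_positions=positions_um,
        n_tiles=n,
    )


def total_volumes(n_fish: int, n_angles: int, tiles_per_fish: int) -> int:
    """Total acquisition volumes per timepoint: fish × angles × tiles."""
    if min(n_fish, n_angles, tiles_per_fish) < 1:
        raise ValueError("counts must be positive integers")
    return n_fish * n_angles * tiles_per_fish


def estimate_data_rate(
    settings: AcquisitionSettings, binary_units: bool = False
) -> dict:
    """Sustained data generation rate of a time-lapse experiment.

    Bytes per timepoint = volumes × channels × planes × frame pixels ×
    bytes/pixel, scaled by timepoints per day. ``binary_units=True``
    reports TiB (2⁴⁰ bytes) instead of TB (10¹² bytes).
    """
    h, w = settings.frame_pixels
    per_timepoint = (
        settings.n_volumes
        * settings.n_channels
        * settings.planes_per_volume
        * h * w
        * settings.bytes_per_pixel
    )
    per_day = per_timepoint * (1440.0 / settings.interval_minutes)
    tb = per_day / (2**40 if binary_units else 1e12)
    return {
        "bytes_per_timepoint": per_timepoint,
        "bytes_per_day": per_day,
        "tb_per_day": tb,
        "units": "TiB" if binary_units else "TB",
    }
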