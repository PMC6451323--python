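"""Volume quantification of segmented vasculature.

Segmented stacks are resampled to isotropic resolution (nearest-neighbour,
so masks stay binary) and segmented voxels are counted; the count times
the isotropic voxel volume gives the vascular volume in µm³. Per-region
volumes intersect the mask with an annotation label image. Measurements
from the two opposite ±60° viewing angles are averaged per fish, and the
series of different fish are aligned in time using a per-fish reference
shift (in the study, the anastomosis of the left and right primordial
hindbrain channels, identified manually).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segmentation import BinaryMask

__all__ = [
    "VolumeSeries",
    "measure_volume",
    "measure_region_volumes",
    "combine_angles",
    "align_time",
    "isotropic_resample",
]


@dataclass
class VolumeSeries:
    """A vascular-volume time series for one fish and one region."""

    fish_id: str
    region: str  # whole | head | tail | plexus | other
    times: np.ndarray  # hours post fertilization, strictly increasing
    volumes: np.ndarray  # µm³
    angle_ids: tuple = ()
    voxel_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.times.shape != self.volumes.shape or self.times.ndim != 1:
            raise ValueError("times and volumes must be parallel 1D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "region": self.region,
                "time_hpf": self.times,
                "volume_um3": self.volumes,
                "n_angles": max(len(self.angle_ids), 1),
            }
        )


def isotropic_resample(mask: BinaryMask) -> tuple[np.ndarray, float]:
    """Nearest-neighbour resample of a mask to isotropic voxels.

    The isotropic target spacing is the finest existing spacing, so no
    information is lost; each output voxel copies its nearest source
    voxel, preserving binarity. Returns the resampled array and the
    isotropic voxel edge length (µm).
    """
    spacing = np.asarray(mask.voxel_spacing, dtype=np.float64)
    iso = float(spacing.min())
    factors = spacing / iso
    indices = []
    for n, f in zip(mask.shape, factors):
        new_n = int(round(n * f))
        # centre-aligned nearest-neighbour index map; exact replication
        # when the factor is an integer
        idx = np.minimum((np.arange(new_n) / f).astype(np.int64), n - 1)
        indices.append(idx)
    out = mask.voxels[np.ix_(*indices)]
    return out, iso


def measure_volume(mask: BinaryMask) -> float:
    """Vascular volume in µm³: isotropic resample, count, scale."""
    iso_mask, iso = isotropic_resample(mask)
    return float(iso_mask.sum()) * iso**3


def measure_region_volumes(mask: BinaryMask, labels: np.ndarray) -> dict[str, float]:
    """Per-region volumes of a mask under an annotation label image.

    ``labels`` is an integer array (0 = unlabeled) or an array of region
    -name strings, shape-matched to the mask. Labels partition the mask:
    per-region volumes plus the ``"other"`` (unlabeled) volume sum
    exactly to the whole-mask volume.
    """
    labels = np.asarray(labels)
    if labels.shape != mask.shape:
        raise ValueError(
            f"label image shape {labels.shape} != mask shape {mask.shape}"
        )
    out: dict[str, float] = {}
    label_values = [v for v in np.unique(labels) if v not in (0, "", "other")]
    covered = np.zeros(mask.shape, dtype=bool)
    for value in label_values:
        region = labels == value
        covered |= region
        sub = BinaryMask(mask.voxels & region, mask.voxel_spacing)
        out[str(value)] = measure_volume(sub)
    other = BinaryMask(mask.voxels & ~covered, mask.voxel_spacing)
    out["other"] = measure_volume(other)
    return out


def combine_angles(series_a: VolumeSeries, series_b: VolumeSeries) -> VolumeSeries:
    """Average the volume measurements of two viewing angles pointwise.

    Timepoints present in only one series are dropped with a warning;
    the series must belong to the same fish and region.
    """
    if series_a.fish_id != series_b.fish_id or series_a.region != series_b.region:
        raise ValueError("can only combine angles of the same fish and region")
    common, ia, ib = np.intersect1d(series_a.times, series_b.times,
                                    return_indices=True)
    if len(common) == 0:
        raise ValueError("series share no timepoints")
    dropped = (len(series_a) - len(common)) + (len(series_b) - len(common))
    if dropped:
        warnings.warn(f"dropped {dropped} unmatched timepoints when combining angles",
                      stacklevel=2)
    return VolumeSeries(
        series_a.fish_id,
        series_a.region,
        common,
        (series_a.volumes[ia] + series_b.volumes[ib]) / 2.0,
        angle_ids=tuple(series_a.angle_ids) + tuple(series_b.angle_ids),
    )


def align_time(series: VolumeSeries, reference_time_shift: float) -> VolumeSeries:
    """Shift the time base by ``reference_time_shift`` hours (volumes untouched)."""
    if not np.isfinite(reference_time_shift):
        raise ValueError("time shift must be finite")
    return replace(series, times=series.times + reference_time_shift)
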