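"""Per-voxel features of the endothelial channel.

The vessel-wall marker labels hollow tubes with heterogeneous wall
intensity, so raw intensity alone cannot separate vessels from background.
The segmentation model instead weighs six first-order features computed
here: the raw signal, the three axial intensity gradients, the total
gradient magnitude, and an inverse-gradient-weighted copy of the raw image
(bright where the signal is strong *and* locally flat, i.e. inside filled
fine vessels, dim on steep wall edges).

Gradients are central differences in voxel units with replicate-edge
boundary handling; axis anisotropy is absorbed by per-feature
standardization at model-fitting time, so no µm scaling is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelVolume", "FeatureStack", "compute_feature_stack", "FEATURE_NAMES"]

FEATURE_NAMES = (
    "raw",
    "grad_x",
    "grad_y",
    "grad_z",
    "grad_total",
    "inv_grad_weighted",
)


@dataclass
class ChannelVolume:
    """A single-channel 3D intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    intensities
        Non-negative 3D array ordered (z, y, x).
    voxel_spacing
        Physical voxel size in µm, ordered (z, y, x).
    channel
        Tag identifying the marker: ``"endothelial"`` (vessel wall) or
        ``"rbc"`` (circulating red blood cells, the luminal proxy source).
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "endothelial"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D array (z, y, x)")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three strictly positive values")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


def _central_diff(volume: np.ndarray, axis: int) -> np.ndarray:
    """Central difference along ``axis`` with replicate-edge padding."""
    pad = [(0, 0)] * volume.ndim
    pad[axis] = (1, 1)
    padded = np.pad(volume, pad, mode="edge")
    hi = [slice(None)] * volume.ndim
    lo = [slice(None)] * volume.ndim
    hi[axis] = slice(2, None)
    lo[axis] = slice(0, -2)
    return (padded[tuple(hi)] - padded[tuple(lo)]) / 2.0


@dataclass
class FeatureStack:
    """Six aligned per-voxel feature maps plus their volume statistics.

    The maps are stored unstandardized (so e.g. ``grad_total`` and
    ``inv_grad_weighted`` are non-negative); ``means``/``sds`` hold the
    per-feature statistics over the whole volume that the segmentation
    model uses for z-scoring, so a model fitted on one stack can score
    another with the training statistics.
    """

    raw: np.ndarray
    grad_x: np.ndarray
    grad_y: np.ndarray
    grad_z: np.ndarray
    grad_total: np.ndarray
    inv_grad_weighted: np.ndarray
    means: np.ndarray = field(default=None, repr=False)
    sds: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps()}
        if len(shapes) != 1:
            raise ValueError("all feature maps must share the source shape")
        if self.means is None or self.sds is None:
            flat = self.as_matrix()
            self.means = flat.mean(axis=0)
            sds = flat.std(axis=0)
            # constant features standardize to all-zero rather than dividing by 0
            sds[sds == 0] = 1.0
            self.sds = sds

    def maps(self) -> tuple[np.ndarray, ...]:
        return (
            self.raw,
            self.grad_x,
            self.grad_y,
            self.grad_z,
            self.grad_total,
            self.inv_grad_weighted,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.raw.shape

    def as_matrix(self) -> np.ndarray:
        """All voxels as an (n_voxels, 6) design matrix, unstandardized."""
        return np.stack([m.ravel() for m in self.maps()], axis=1)

    def standardized_at(
        self,
        coordinates: np.ndarray,
        means: np.ndarray | None = None,
        sds: np.ndarray | None = None,
    ) -> np.ndarray:
        """Z-scored feature rows at integer (z, y, x) ``coordinates``."""
        means = self.means if means is None else means
        sds = self.sds if sds is None else sds
        coords = np.asarray(coordinates)
        idx = tuple(coords.T)
        rows = np.stack([m[idx] for m in self.maps()], axis=1)
        return (rows - means) / sds


def compute_feature_stack(volume: ChannelVolume) -> FeatureStack:
    """Compute the six segmentation features of an endothelial volume.

    Features: (1) raw intensity, (2–4) central-difference gradients along
    x, y, z, (5) the Euclidean gradient magnitude, and (6) the
    inverse-gradient-weighted image ``raw / (1 + |∇I|)``.

    Raises
    ------
    ValueError
        If any axis has fewer than 3 voxels (no interior for a central
        difference).
    """
    data = volume.intensities
    if min(data.shape) < 3:
        raise ValueError(
            f"volume too thin for gradient features: shape {data.shape}, "
            "need >= 3 voxels per axis"
        )
    # axes are (z, y, x): feature 2 is the x gradient = axis 2
    gx = _central_diff(data, 2)
    gy = _central_diff(data, 1)
    gz = _central_diff(data, 0)
    gtot = np.sqrt(gx**2 + gy**2 + gz**2)
    inv_grad = data / (1.0 + gtot)
    return FeatureStack(data.copy(), gx, gy, gz, gtot, inv_grad)
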