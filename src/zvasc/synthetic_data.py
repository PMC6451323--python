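"""Synthetic two-channel vascular phantoms, tile sets and growth series.

Every downstream stage of the pipeline is testable against these
generators without the study's raw imagery. The vessel phantom emulates
the two transgenic markers of the imaging experiment:

* endothelial channel — hollow tubes whose walls carry a Gaussian-shell
  intensity profile with multiplicative heterogeneity (bright blobs where
  endothelial nuclei sit), blurred by an isotropic Gaussian approximating
  the optical point-spread function. The PSF matters scientifically: at
  capillary scale it partially fills lumina with wall signal, which is
  the property the RBC-supervised segmentation exploits on real data.
* RBC channel — ellipsoidal speckles (circulating red blood cells) whose
  centres lie strictly inside the true lumina.

Ground-truth wall, lumen and vessel (wall ∪ lumen) masks are returned
with the volumes. Tile sets cut a volume along one axis with a fixed
overlap and known integer jitter on the true offsets; growth series
evaluate a named growth model on an even time grid plus Gaussian noise.
All randomness in one generator call derives from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .features import ChannelVolume
from .growth import MODELS, model_value
from .quantify import VolumeSeries
from .stitching import TileSet

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "GrowthSeriesSpec",
    "generate_vessel_phantom",
    "generate_tile_set",
    "generate_growth_series",
    "write_phantom",
    "read_phantom",
]

#: approximate embryonic RBC half-axes (z, y, x) in µm; zebrafish
#: erythrocytes are nucleated ellipsoids roughly 7×5 µm across
RBC_SIGMA_UM = (1.2, 1.0, 1.0)
#: endothelial nucleus blob radius (µm) for wall-intensity heterogeneity
NUCLEUS_SIGMA_UM = 2.0
#: cell-free clearance (µm) between RBC centres and the inner wall face;
#: circulating cells travel in the axial stream, off the wall
RBC_WALL_CLEARANCE_UM = 1.5


@dataclass
class PhantomSpec:
    """Parameters of a two-channel vessel phantom.

    All physical quantities are in µm; intensities are arbitrary units.
    ``psf_sigma`` is the isotropic Gaussian optical blur applied to the
    endothelial channel; ``lumen_fill`` is the luminal signal level as a
    fraction of the wall intensity (cytosolic marker lining, PSF fill
    and scattered light keep real vessel interiors above background —
    the property the RBC-supervised training depends on).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_vessels: int = 3
    radius_range: tuple[float, float] = (4.0, 7.0)
    wall_thickness: float = 1.0
    wall_intensity_range: tuple[float, float] = (120.0, 255.0)
    nucleus_density: float = 0.15  # nuclei per µm of centerline
    rbc_density: float = 0.04  # speckles per µm³ of lumen
    noise_sigma: float = 0.0
    psf_sigma: float = 1.5
    lumen_fill: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        extent = min(n * s for n, s in zip(self.shape, self.voxel_spacing))
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("shape and voxel_spacing must be strictly positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        r_lo, r_hi = self.radius_range
        if not 0 < r_lo <= r_hi:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if r_hi >= extent / 4.0:
            raise ValueError(
                f"max radius {r_hi} µm cannot fit: must be < min physical "
                f"extent / 4 = {extent / 4.0:.2f} µm"
            )
        if not 0 < self.wall_thickness < r_lo:
            raise ValueError("wall_thickness must be in (0, radius min)")
        if self.nucleus_density < 0 or self.rbc_density < 0 or self.noise_sigma < 0:
            raise ValueError("densities and noise_sigma must be >= 0")
        if not 0 <= self.lumen_fill < 1:
            raise ValueError("lumen_fill must be in [0, 1)")


@dataclass
class PhantomVolume:
    """A generated phantom: both channels plus ground-truth masks."""

    endothelial: ChannelVolume
    rbc: ChannelVolume
    truth_wall: np.ndarray
    truth_lumen: np.ndarray
    truth_vessel: np.ndarray
    rbc_centers: np.ndarray | None = field(default=None, repr=False)
    spec: PhantomSpec | None = field(default=None, repr=False)


def _centerline_points(rng, shape_um, radius, step_um=0.5, max_turn=0.15):
    """A bounded-curvature random-walk polyline, densely sampled.

    The walk starts at a random interior point, takes fixed-length steps
    whose direction rotates by at most ``max_turn`` radians per µm, and
    reflects off a margin of one radius from the volume faces. Length is
    ~1.5× the largest physical extent, enough to traverse the volume.
    """
    margin = radius + 1.0
    lo = np.full(3, margin)
    hi = np.asarray(shape_um) - margin
    if np.any(hi <= lo):
        raise ValueError(
            f"vessel of radius {radius:.2f} µm cannot fit inside the volume"
        )
    pos = rng.uniform(lo, hi)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    n_steps = int(1.5 * max(shape_um) / step_um)
    points = [pos.copy()]
    for _ in range(n_steps):
        turn = rng.normal(0.0, max_turn * step_um, size=3)
        direction = direction + turn
        direction /= np.linalg.norm(direction)
        pos = pos + direction * step_um
        for d in range(3):  # reflect off the margin planes
            if pos[d] < lo[d]:
                pos[d] = 2 * lo[d] - pos[d]
                direction[d] = abs(direction[d])
            elif pos[d] > hi[d]:
                pos[d] = 2 * hi[d] - pos[d]
                direction[d] = -abs(direction[d])
        points.append(pos.copy())
    return np.array(points)


def _distance_to_centerline(points_um, shape, spacing):
    """Per-voxel Euclidean distance (µm) to the rasterized centerline."""
    seed_mask = np.ones(shape, dtype=bool)
    idx = np.round(points_um / np.asarray(spacing)).astype(np.int64)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    seed_mask[tuple(idx.T)] = False
    return ndimage.distance_transform_edt(seed_mask, sampling=spacing)


def _add_blob(accum, center_um, sigma_um, amplitude, spacing):
    """Add a Gaussian blob (possibly anisotropic) at a physical position."""
    spacing = np.asarray(spacing)
    sigma_vox = np.asarray(sigma_um) / spacing
    center_vox = np.asarray(center_um) / spacing
    lo = np.maximum(np.floor(center_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1,
                    np.asarray(accum.shape))
    if np.any(hi <= lo):
        return
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_vox, sigma_vox))
    accum[tuple(slice(a, b) for a, b in zip(lo, hi))] += amplitude * np.exp(-0.5 * q)


def generate_vessel_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate a two-channel vessel phantom with ground truth.

    Each vessel is a random-walk tube of constant radius. The wall mask
    is the shell ``|d − r| ≤ w/2`` of the distance ``d`` to the
    centerline; the lumen is ``d < r − w/2``; the vessel truth is their
    union. Endothelial intensity follows a Gaussian shell centred at the
    radius, modulated by bright nucleus blobs along the centerline, then
    blurred by the PSF; RBC speckles are placed with centres strictly
    inside the lumen, keeping the cell-free clearance off the wall that
    circulating cells show in vivo. With ``n_vessels=0`` both channels
    are pure noise and all truth masks are empty. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.voxel_spacing)
    shape_um = np.asarray(shape) * spacing

    endo = np.zeros(shape, dtype=np.float64)
    rbc = np.zeros(shape, dtype=np.float64)
    wall = np.zeros(shape, dtype=bool)
    lumen = np.zeros(shape, dtype=bool)
    all_rbc_centers: list = []
    half_w = spec.wall_thickness / 2.0
    shell_sigma = spec.wall_thickness / 2.0

    for _ in range(spec.n_vessels):
        radius = rng.uniform(*spec.radius_range)
        pts = _centerline_points(rng, shape_um, radius)
        dist = _distance_to_centerline(pts, shape, spacing)

        v_wall = np.abs(dist - radius) <= half_w
        v_lumen = dist < radius - half_w
        wall |= v_wall
        lumen |= v_lumen

        # Gaussian shell centred at the wall radius, zero well outside;
        # inside the lumen a weak cytosolic/scatter fill keeps vessel
        # interiors above extravascular background, as in real data where
        # cytosolic EGFP and out-of-focus light fill the tubes
        shell = np.exp(-0.5 * ((dist - radius) / shell_sigma) ** 2)
        shell[dist > radius + 4 * shell_sigma] = 0.0
        shell = np.maximum(shell, spec.lumen_fill * (dist < radius))

        # multiplicative heterogeneity: bright endothelial nuclei along
        # the centerline (Poisson-distributed per µm of centerline)
        length_um = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        heterogeneity = np.zeros(shape)
        for _ in range(rng.poisson(spec.nucleus_density * length_um)):
            k = rng.integers(len(pts))
            _add_blob(heterogeneity, pts[k], (NUCLEUS_SIGMA_UM,) * 3,
                      rng.uniform(0.8, 1.6), spacing)
        base = rng.uniform(*spec.wall_intensity_range)
        endo += base * shell * (1.0 + heterogeneity)

        # RBC speckles: homogeneous Poisson process over the luminal
        # interior, kept off the wall like circulating cells
        interior = dist < max(radius - half_w - RBC_WALL_CLEARANCE_UM, 0.3 * radius)
        centres = np.argwhere(interior)
        if len(centres):
            lumen_um3 = float(v_lumen.sum()) * float(np.prod(spacing))
            n_rbc = rng.poisson(spec.rbc_density * lumen_um3)
            for k in rng.integers(len(centres), size=n_rbc):
                c_um = centres[k] * spacing
                _add_blob(rbc, c_um, RBC_SIGMA_UM,
                          rng.uniform(0.5, 1.0) * 200.0, spacing)
                all_rbc_centers.append(centres[k])

    # lumen wins where overlapping vessels disagree (wall of one tube
    # passing through the lumen of another is open, not signal)
    wall &= ~lumen

    if spec.psf_sigma > 0 and spec.n_vessels > 0:
        endo = ndimage.gaussian_filter(endo, spec.psf_sigma / spacing)

    if spec.noise_sigma > 0:
        endo = endo + rng.normal(0.0, spec.noise_sigma, shape)
        rbc = rbc + rng.normal(0.0, spec.noise_sigma, shape)
    np.clip(endo, 0.0, None, out=endo)
    np.clip(rbc, 0.0, None, out=rbc)

    vspace = tuple(spec.voxel_spacing)
    return PhantomVolume(
        ChannelVolume(endo, vspace, "endothelial"),
        ChannelVolume(rbc, vspace, "rbc"),
        truth_wall=wall,
        truth_lumen=lumen,
        truth_vessel=wall | lumen,
        rbc_centers=(np.array(all_rbc_centers, dtype=np.int64)
                     if all_rbc_centers else np.empty((0, 3), dtype=np.int64)),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# tile sets
# ---------------------------------------------------------------------------

def generate_tile_set(
    volume: np.ndarray,
    n_tiles: int,
    overlap_fraction: float = 0.3,
    jitter_px: int = 0,
    seed: int = 0,
) -> TileSet:
    """Cut a volume into overlapping tiles along its last axis.

    The tile width ``w`` satisfies ``w + (n−1)·(1−overlap)·w = L`` so the
    nominal spacing implies exactly ``overlap_fraction`` overlap; true
    offsets add integer jitter in ``[−jitter_px, +jitter_px]`` (tile 0
    anchors the frame at 0) and tiles are cut at the true offsets, so
    reassembly at the true offsets reproduces the source exactly.
    Nominal and true offsets are both stored on the returned
    :class:`~zvasc.stitching.TileSet`.
    """
    volume = np.asarray(volume)
    if not 0 < overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in (0, 1)")
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    L = volume.shape[-1]
    ndim = volume.ndim
    if n_tiles == 1:
        positions = np.zeros((1, ndim), dtype=np.int64)
        return TileSet([volume.copy()], positions, true_positions=positions.copy())

    width = int(round(L / (1.0 + (n_tiles - 1) * (1.0 - overlap_fraction))))
    step = int(round((1.0 - overlap_fraction) * width))
    if step < 1 or width < 2:
        raise ValueError(
            f"overlap {overlap_fraction} too large to place {n_tiles} distinct "
            f"tiles in extent {L}"
        )
    rng = np.random.default_rng(seed)
    nominal_x = np.arange(n_tiles, dtype=np.int64) * step
    jitter = rng.integers(-jitter_px, jitter_px + 1, size=n_tiles) if jitter_px else \
        np.zeros(n_tiles, dtype=np.int64)
    jitter[0] = 0
    true_x = np.clip(nominal_x + jitter, 0, L - width)
    if true_x[-1] + width > L or np.any(np.diff(true_x) <= 0):
        raise ValueError("tiles do not fit distinctly in the volume")

    tiles = [volume[..., x : x + width].copy() for x in true_x]
    nominal = np.zeros((n_tiles, ndim), dtype=np.int64)
    nominal[:, -1] = nominal_x
    true = np.zeros((n_tiles, ndim), dtype=np.int64)
    true[:, -1] = true_x
    return TileSet(tiles, nominal, true_positions=true)


# ---------------------------------------------------------------------------
# growth series
# ---------------------------------------------------------------------------

@dataclass
class GrowthSeriesSpec:
    """Parameters of a simulated volume-growth time series."""

    model_id: str = "log_logistic"
    params: dict = field(default_factory=lambda: {
        "A": 2.0e6, "V_L": 1.2e7, "alpha": 32.0, "beta": 3.0,
    })
    t_start: float = 17.0  # hpf, the study's imaging start
    t_end: float = 90.0  # ~3 days of imaging
    n_points: int = 100
    noise_sigma: float = 0.0  # volume units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.t_start <= 0 or self.t_end <= self.t_start:
            raise ValueError("need 0 < t_start < t_end")
        n_free = len(MODELS[self.model_id].param_names)
        if self.n_points < 4 + n_free:
            raise ValueError(f"n_points must be >= {4 + n_free} for {self.model_id}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_growth_series(spec: GrowthSeriesSpec) -> VolumeSeries:
    """Evaluate a growth model on an even time grid plus Gaussian noise.

    ``volume_i = model(t_i; params) + ε_i`` with ``ε_i ~ N(0, σ²)``;
    deterministic for a fixed seed. Invalid parameters (e.g. σ ≤ 0 for
    the log-normal model) are rejected by the model definitions.
    """
    t = np.linspace(spec.t_start, spec.t_end, spec.n_points)
    v = model_value(spec.model_id, spec.params, t)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sigma, size=v.shape)
    return VolumeSeries("synthetic", "whole", t, v)


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def write_phantom(phantom: PhantomVolume, directory) -> dict:
    """Write a phantom as per-channel multi-page TIFFs + a sidecar JSON.

    One TIFF per channel (z-planes as pages), ground-truth masks as
    8-bit TIFFs, and ``phantom.json`` holding spacing, seed and the full
    generation spec. Returns the mapping of written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("endothelial", phantom.endothelial), ("rbc", phantom.rbc)):
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, vol.intensities.astype(np.float32))
        paths[name] = p
    for name, mask in (
        ("truth_wall", phantom.truth_wall),
        ("truth_lumen", phantom.truth_lumen),
        ("truth_vessel", phantom.truth_vessel),
    ):
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, (mask.astype(np.uint8) * 255))
        paths[name] = p
    meta = {
        "voxel_spacing_um": list(phantom.endothelial.voxel_spacing),
        "spec": asdict(phantom.spec) if phantom.spec is not None else None,
    }
    meta_path = directory / "phantom.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["meta"] = meta_path
    return paths


def read_phantom(directory) -> PhantomVolume:
    """Read a phantom written by :func:`write_phantom`."""
    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    spacing = tuple(meta["voxel_spacing_um"])
    endo = tifffile.imread(directory / "endothelial.tif")
    rbc = tifffile.imread(directory / "rbc.tif")
    masks = {
        name: tifffile.imread(directory / f"{name}.tif") > 0
        for name in ("truth_wall", "truth_lumen", "truth_vessel")
    }
    spec = PhantomSpec(**{**meta["spec"], "shape": tuple(meta["spec"]["shape"]),
                          "voxel_spacing": tuple(meta["spec"]["voxel_spacing"]),
                          "radius_range": tuple(meta["spec"]["radius_range"]),
                          "wall_intensity_range": tuple(meta["spec"]["wall_intensity_range"])}) \
        if meta.get("spec") else None
    return PhantomVolume(
        ChannelVolume(endo, spacing, "endothelial"),
        ChannelVolume(rbc, spacing, "rbc"),
        masks["truth_wall"], masks["truth_lumen"], masks["truth_vessel"],
        spec=spec,
    )


def write_tile_offsets(tileset: TileSet, path) -> None:
    """True/nominal tile offsets as a headered CSV."""
    ndim = tileset.ndim
    cols = ["z", "y", "x"][-ndim:]
    rows = []
    for i in range(len(tileset.tiles)):
        row = {"tile_id": i}
        row.update({f"nominal_{c}": tileset.nominal_positions[i, d]
                    for d, c in enumerate(cols)})
        if tileset.true_positions is not None:
            row.update({f"true_{c}": tileset.true_positions[i, d]
                        for d, c in enumerate(cols)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_growth_series(series: VolumeSeries, path) -> None:
    """Growth series as a headered CSV consumable by the growth module."""
    series.to_frame().to_csv(path, index=False)
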