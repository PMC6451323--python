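"""Phase-correlation stitching of overlapping acquisition volumes.

Tiles come with nominal positions from the translational stages, which are
precise enough to bound the search: phase correlation proposes candidate
integer offsets near the nominal displacement, real-space normalized
cross-correlation of the implied overlap picks the best, and a weighted
least-squares globalization reconciles all pairwise offsets into one
consistent placement. Fusion uses linear blending with distance-to-border
ramps. Registration runs on y/x maximum-intensity projections and the
resulting 2D offsets are applied to the 3D stacks (z offsets are taken
from the stage positions).

Conventions: 0-based voxel indices; an offset is the (z, y, x) — or (y, x)
in 2D — displacement of a tile's origin in the global frame. Offsets are
integer voxels throughout; stage repeatability is sub-pixel, and binary
masks must survive stitching unresampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft
from scipy.ndimage import maximum_filter
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "TileSet",
    "PairwiseOffset",
    "phase_correlation_offset",
    "globalize_offsets",
    "fuse_linear_blending",
    "stitch_dataset",
    "max_project",
]

#: real-space correlation below this is treated as an unreliable link and
#: the registration falls back to the nominal (stage) displacement
DEFAULT_SCORE_FLOOR = 0.3
DEFAULT_SEARCH_RADIUS = 20
#: weight given to nominal-fallback links in the globalization solve
FALLBACK_WEIGHT = 1e-3


@dataclass
class TileSet:
    """Overlapping image tiles with nominal and (optionally) refined positions.

    ``tiles`` are all 2D or all 3D arrays; positions are integer voxel
    offsets of each tile origin. ``adjacency`` lists index pairs expected
    to overlap; if empty it is derived from the nominal positions.
    ``true_positions`` is only populated by the synthetic generator.
    """

    tiles: list
    nominal_positions: np.ndarray
    refined_positions: np.ndarray | None = None
    adjacency: list = field(default_factory=list)
    true_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tiles = [np.asarray(t, dtype=np.float64) for t in self.tiles]
        if not self.tiles:
            raise ValueError("tile set is empty")
        ndim = self.tiles[0].ndim
        if any(t.ndim != ndim for t in self.tiles):
            raise ValueError("tiles must share dimensionality")
        self.nominal_positions = np.asarray(self.nominal_positions, dtype=np.int64)
        if self.nominal_positions.shape != (len(self.tiles), ndim):
            raise ValueError("one nominal position per tile, matching dimensionality")
        if not self.adjacency:
            self.adjacency = self._derive_adjacency()

    @property
    def ndim(self) -> int:
        return self.tiles[0].ndim

    def _derive_adjacency(self) -> list:
        pairs = []
        for i in range(len(self.tiles)):
            for j in range(i + 1, len(self.tiles)):
                if _overlap_voxels(
                    self.nominal_positions[i],
                    self.tiles[i].shape,
                    self.nominal_positions[j],
                    self.tiles[j].shape,
                ) > 0:
                    pairs.append((i, j))
        return pairs


def _overlap_voxels(pos_a, shape_a, pos_b, shape_b) -> int:
    n = 1
    for pa, sa, pb, sb in zip(pos_a, shape_a, pos_b, shape_b):
        lo = max(pa, pb)
        hi = min(pa + sa, pb + sb)
        if hi <= lo:
            return 0
        n *= hi - lo
    return int(n)


def _overlap_views(a: np.ndarray, b: np.ndarray, offset: np.ndarray):
    """Views of a and b on the region where b placed at ``offset`` overlaps a."""
    sl_a, sl_b = [], []
    for d in range(a.ndim):
        lo = max(0, offset[d])
        hi = min(a.shape[d], offset[d] + b.shape[d])
        if hi <= lo:
            return None, None
        sl_a.append(slice(lo, hi))
        sl_b.append(slice(lo - offset[d], hi - offset[d]))
    return a[tuple(sl_a)], b[tuple(sl_b)]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape arrays."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        # flat overlap carries no registration signal
        return 0.0
    return float(np.dot(a, b) / denom)


@dataclass
class PairwiseOffset:
    """Result of registering one tile pair."""

    i: int
    j: int
    offset: np.ndarray  # displacement of tile j relative to tile i
    score: float
    reliable: bool


def phase_correlation_offset(
    a: np.ndarray,
    b: np.ndarray,
    init_offset,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    n_peaks: int = 8,
):
    """Integer offset of image ``b`` relative to ``a`` by phase correlation.

    The normalized cross-power spectrum is inverted to a correlation
    surface whose strongest peaks are candidate offsets (each peak is
    ambiguous modulo the padded extent; all congruent candidates within
    ``search_radius`` of ``init_offset`` are considered). Candidates are
    ranked by real-space normalized cross-correlation of the implied
    overlap, which resolves the wraparound ambiguity and rejects spurious
    spectral peaks.

    Returns
    -------
    (offset, score, reliable)
        ``offset`` is an integer array; if no candidate scores above
        ``score_floor`` the nominal ``init_offset`` is returned with
        ``reliable=False``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != b.ndim:
        raise ValueError("images must share dimensionality")
    init_offset = np.asarray(init_offset, dtype=np.int64)
    ov_a, _ = _overlap_views(a, b, init_offset)
    if ov_a is None or ov_a.size < 0.1 * min(a.size, b.size):
        raise ValueError("tiles must overlap by >= 10% of a tile at the initial offset")

    shape = tuple(max(sa, sb) for sa, sb in zip(a.shape, b.shape))
    fa = spfft.fftn(a, shape)
    fb = spfft.fftn(b, shape)
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = spfft.ifftn(cross / mag).real

    # local maxima of the correlation surface, strongest first
    footprint = maximum_filter(corr, size=3, mode="wrap")
    peak_idx = np.flatnonzero((corr == footprint).ravel())
    order = np.argsort(corr.ravel()[peak_idx])[::-1][:n_peaks]
    peaks = np.array(np.unravel_index(peak_idx[order], shape)).T

    best = (None, -np.inf)
    for peak in peaks:
        # each peak coordinate is the shift modulo the FFT extent
        for cand in _congruent_offsets(peak, shape, init_offset, search_radius):
            ov_a_c, ov_b_c = _overlap_views(a, b, cand)
            if ov_a_c is None or ov_a_c.size < 0.01 * min(a.size, b.size):
                continue
            score = _ncc(ov_a_c, ov_b_c)
            if score > best[1]:
                best = (cand, score)

    offset, score = best
    if offset is None or score < score_floor:
        return init_offset.copy(), (score if offset is not None else 0.0), False
    return offset, score, True


def _congruent_offsets(peak, shape, init_offset, radius):
    """All offsets congruent to ``peak`` mod ``shape`` within ``radius`` of init."""
    axes_choices = []
    for p, n, c in zip(peak, shape, init_offset):
        lo = int(np.floor((c - radius - p) / n))
        hi = int(np.ceil((c + radius - p) / n))
        choices = [p + k * n for k in range(lo, hi + 1)
                   if abs(p + k * n - c) <= radius]
        if not choices:
            return
        axes_choices.append(choices)
    grids = np.meshgrid(*axes_choices, indexing="ij")
    for cand in np.stack([g.ravel() for g in grids], axis=1):
        yield cand.astype(np.int64)


def globalize_offsets(
    pairwise: list,
    nominal_positions: np.ndarray,
    fallback_weight: float = FALLBACK_WEIGHT,
) -> np.ndarray:
    """Consistent global tile positions from pairwise offsets.

    Tile 0 is pinned at the origin; remaining positions minimize the
    score-weighted sum of squared deviations from the measured pairwise
    displacements (independent linear least squares per axis). Pairs
    flagged unreliable contribute their nominal displacement with weight
    ``fallback_weight`` so the graph stays connected without letting a bad
    registration pull the solution.
    """
    nominal = np.asarray(nominal_positions, dtype=np.float64)
    n, ndim = nominal.shape
    if n == 1:
        return np.zeros((1, ndim), dtype=np.int64)

    rows_i, rows_j, weights, rhs = [], [], [], []
    for p in pairwise:
        if p.reliable:
            w, d = max(p.score, fallback_weight), np.asarray(p.offset, float)
        else:
            w, d = fallback_weight, nominal[p.j] - nominal[p.i]
        rows_i.append(p.i)
        rows_j.append(p.j)
        weights.append(w)
        rhs.append(d)

    adj = csr_matrix(
        (np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(f"tile adjacency graph is disconnected: components {comps}")

    # unknowns: positions 1..n-1 (tile 0 fixed at origin)
    m = len(rows_i)
    A = np.zeros((m, n - 1))
    B = np.zeros((m, ndim))
    for r, (i, j, w, d) in enumerate(zip(rows_i, rows_j, weights, rhs)):
        sw = np.sqrt(w)
        if j > 0:
            A[r, j - 1] += sw
        if i > 0:
            A[r, i - 1] -= sw
        B[r] = sw * d
    sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    positions = np.vstack([np.zeros(ndim), sol])
    return np.round(positions).astype(np.int64)


def fuse_linear_blending(tiles: list, positions: np.ndarray) -> np.ndarray:
    """Fuse tiles at the given positions with linear blending.

    Each tile contributes with a weight ramp proportional to its distance
    to the nearest tile border (the Fiji-style blending ramp), normalized
    across contributing tiles; voxels covered by a single tile are copied
    unchanged. Positions are shifted so the fused canvas starts at 0.
    """
    if not tiles:
        raise ValueError("no tiles to fuse")
    tiles = [np.asarray(t, dtype=np.float64) for t in tiles]
    positions = np.asarray(positions, dtype=np.int64)
    positions = positions - positions.min(axis=0)
    extent = tuple(
        int(max(p + s for p, s in zip(positions[:, d], (t.shape[d] for t in tiles))))
        for d in range(tiles[0].ndim)
    )
    acc = np.zeros(extent)
    wacc = np.zeros(extent)
    cover = np.zeros(extent, dtype=np.int32)
    for tile, pos in zip(tiles, positions):
        w = _border_ramp(tile.shape)
        sl = tuple(slice(p, p + s) for p, s in zip(pos, tile.shape))
        acc[sl] += w * tile
        wacc[sl] += w
        cover[sl] += 1
    with np.errstate(invalid="ignore"):
        fused = acc / wacc
    fused[wacc == 0] = 0.0
    # voxels covered by exactly one tile are copied unchanged (bit-exact)
    for tile, pos in zip(tiles, positions):
        sl = tuple(slice(p, p + s) for p, s in zip(pos, tile.shape))
        single = cover[sl] == 1
        fused[sl][single] = tile[single]
    return fused


def _border_ramp(shape) -> np.ndarray:
    """Per-voxel min distance to the tile border (>= 1 everywhere)."""
    ramps = []
    for n in shape:
        i = np.arange(n, dtype=np.float64)
        ramps.append(np.minimum(i + 1, n - i))
    out = ramps[0]
    for r in ramps[1:]:
        out = np.minimum.outer(out, r)
    return out


def max_project(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection along ``axis``."""
    volume = np.asarray(volume)
    if not -volume.ndim <= axis < volume.ndim:
        raise ValueError(f"invalid projection axis {axis} for ndim {volume.ndim}")
    return volume.max(axis=axis)


def register_tiles_2d(
    tiles: list,
    nominal_positions: np.ndarray,
    adjacency: list,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> tuple[np.ndarray, list]:
    """Pairwise registration + globalization of 2D tiles."""
    nominal = np.asarray(nominal_positions, dtype=np.int64)
    pairwise = []
    for i, j in adjacency:
        init = nominal[j] - nominal[i]
        offset, score, reliable = phase_correlation_offset(
            tiles[i], tiles[j], init, search_radius, score_floor
        )
        pairwise.append(PairwiseOffset(i, j, offset, score, reliable))
    return globalize_offsets(pairwise, nominal), pairwise


def stitch_dataset(
    tileset: TileSet,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Stitch a tile set; 3D stacks are registered on their y/x MIPs.

    For 3D input, registration runs on maximum-intensity projections
    along z and the recovered in-plane offsets are applied to the stacks;
    z offsets come from the nominal stage positions (relative to tile 0).
    Returns the fused image and the refined per-tile positions, which are
    also stored on the tile set.
    """
    nominal = tileset.nominal_positions
    if len(tileset.tiles) == 1:
        tileset.refined_positions = np.zeros_like(nominal)
        return tileset.tiles[0].copy(), tileset.refined_positions

    if tileset.ndim == 2:
        refined, _ = register_tiles_2d(
            tileset.tiles, nominal, tileset.adjacency, search_radius, score_floor
        )
    else:
        mips = [max_project(t, axis=0) for t in tileset.tiles]
        refined_yx, _ = register_tiles_2d(
            mips, nominal[:, 1:], tileset.adjacency, search_radius, score_floor
        )
        z = nominal[:, :1] - nominal[0, :1]
        refined = np.hstack([z, refined_yx])

    tileset.refined_positions = refined
    fused = fuse_linear_blending(tileset.tiles, refined)
    return fused, refined
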