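"""Backward ROI propagation through a maximum-intensity-projection series.

Anatomical regions (head, tail, caudal vein plexus) are drawn manually
once, at the *last* timepoint when the anatomy is clearest, and tracked
backward in time. The ROI boundary is discretized into points; for every
point, a 70×70 px template around it at time t is matched, by normalized
cross-correlation, inside a 140×140 px concentric search window at time
t−1. The per-point shifts are regularized by a componentwise median over
seven neighbouring boundary points, and boundary points that land on the
same or neighbouring pixel are merged. Iterating from the last frame to
the first yields the full ROI trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.feature import match_template as _skimage_match_template

__all__ = [
    "BoundaryRoi",
    "match_template",
    "regularize_shifts",
    "merge_boundary_points",
    "propagate_roi",
    "rasterize_roi",
    "read_rois_csv",
    "write_rois_csv",
]

TEMPLATE_SIZE = 70  # px, crop around each boundary point at time t
SEARCH_SIZE = 140  # px, concentric search window at time t−1
MEDIAN_WINDOW = 7  # boundary points entering the shift median


class RoiCollapseError(RuntimeError):
    """Merging reduced an ROI below 3 points; ``timepoint`` says when."""

    def __init__(self, message: str, timepoint: int | None = None):
        super().__init__(message)
        self.timepoint = timepoint


@dataclass
class BoundaryRoi:
    """A closed polygon ROI at one timepoint, as ordered (y, x) points."""

    timepoint: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (y, x)")
        if len(self.points) < 3:
            raise ValueError("a boundary ROI needs at least 3 points")


def match_template(search_image: np.ndarray, template: np.ndarray):
    """Best placement of ``template`` inside ``search_image`` by ZNCC.

    Normalized cross-correlation is evaluated at every valid placement;
    the argmax (top-left corner as (y, x)) and its score are returned.
    Ties are broken by smallest displacement from the window centre,
    then row-major order. A zero-variance template has no defined
    correlation: the centred placement is returned flagged degenerate.

    Returns
    -------
    (position, score, degenerate)
    """
    search = np.asarray(search_image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if template.shape[0] > search.shape[0] or template.shape[1] > search.shape[1]:
        raise ValueError("template must fit inside the search image")
    center = (np.asarray(search.shape) - np.asarray(template.shape)) // 2
    if template.std() == 0:
        return center, float("nan"), True
    corr = _skimage_match_template(search, template, pad_input=False)
    best = np.nanmax(corr)
    ties = np.argwhere(corr >= best - 1e-12)
    disp = np.abs(ties - center).sum(axis=1)
    # stable argmin: smallest displacement, then row-major (argwhere order)
    pos = ties[int(np.argmin(disp))]
    return pos, float(best), False


def regularize_shifts(raw_shifts: np.ndarray) -> np.ndarray:
    """Componentwise median of each shift over 7 neighbouring points.

    The window is circular (the boundary is a closed polygon) and
    centred: the point itself plus three neighbours on each side. Lists
    shorter than 7 points fall back to the global median.
    """
    shifts = np.asarray(raw_shifts, dtype=np.float64)
    if shifts.ndim != 2 or shifts.shape[1] != 2 or len(shifts) == 0:
        raise ValueError("raw_shifts must be a non-empty (n, 2) array")
    n = len(shifts)
    if n < MEDIAN_WINDOW:
        return np.tile(np.median(shifts, axis=0), (n, 1))
    half = MEDIAN_WINDOW // 2
    out = np.empty_like(shifts)
    for i in range(n):
        idx = (np.arange(i - half, i + half + 1)) % n
        out[i] = np.median(shifts[idx], axis=0)
    return out


def merge_boundary_points(points: np.ndarray, timepoint: int | None = None) -> np.ndarray:
    """Drop boundary points landing on the same or an adjacent pixel.

    Scanning in polygon order, a point identical or 8-adjacent
    (Chebyshev distance ≤ 1) to the previously *kept* point is removed.
    Collapsing below 3 points raises :class:`RoiCollapseError`.
    """
    pts = np.asarray(points, dtype=np.int64)
    kept = [pts[0]]
    for p in pts[1:]:
        if np.max(np.abs(p - kept[-1])) > 1:
            kept.append(p)
    if len(kept) < 3:
        raise RoiCollapseError(
            f"ROI collapsed to {len(kept)} points after merging", timepoint
        )
    return np.array(kept, dtype=np.int64)


def _clipped_window(image: np.ndarray, center: np.ndarray, size: int):
    """A size×size window about ``center``, clipped at the image border."""
    half = size // 2
    lo = np.maximum(center - half, 0)
    hi = np.minimum(center - half + size, image.shape)
    return image[lo[0]:hi[0], lo[1]:hi[1]], lo


def propagate_roi(
    mip_series: list[np.ndarray],
    roi_at_last: BoundaryRoi,
    template_size: int = TEMPLATE_SIZE,
    search_size: int = SEARCH_SIZE,
) -> list[BoundaryRoi]:
    """Track an ROI backward from the last frame through a MIP series.

    For each step t → t−1 and each boundary point: a
    ``template_size``² crop about the point at t is matched inside the
    concentric ``search_size``² window at t−1; the raw shift is the best
    match position minus the current position, regularized with the
    median-of-7, applied, and near-duplicate points merged. Windows
    reaching beyond the image are clipped. Returns ROIs ordered by
    timepoint (index 0 first); an ROI collapse aborts with the
    timepoint in the error.
    """
    if len(mip_series) == 0:
        raise ValueError("empty projection series")
    frames = [np.asarray(f, dtype=np.float64) for f in mip_series]
    n_frames = len(frames)
    rois = {n_frames - 1: BoundaryRoi(n_frames - 1, roi_at_last.points.copy())}

    for t in range(n_frames - 1, 0, -1):
        cur = rois[t]
        prev_frame, cur_frame = frames[t - 1], frames[t]
        raw = np.zeros((len(cur.points), 2))
        for k, point in enumerate(cur.points):
            template, _ = _clipped_window(cur_frame, point, template_size)
            search, search_lo = _clipped_window(prev_frame, point, search_size)
            if (template.shape[0] > search.shape[0]
                    or template.shape[1] > search.shape[1]):
                continue  # border-clipped beyond usefulness: keep the point
            pos, _, degenerate = match_template(search, template)
            if degenerate:
                continue
            # centre of the matched template in t−1 frame coordinates
            matched_center = search_lo + pos + np.asarray(template.shape) // 2
            template_center = np.maximum(point - template_size // 2, 0) \
                + np.asarray(template.shape) // 2
            raw[k] = matched_center - template_center
        effective = regularize_shifts(raw)
        moved = np.round(cur.points + effective).astype(np.int64)
        moved[:, 0] = np.clip(moved[:, 0], 0, prev_frame.shape[0] - 1)
        moved[:, 1] = np.clip(moved[:, 1], 0, prev_frame.shape[1] - 1)
        merged = merge_boundary_points(moved, timepoint=t - 1)
        rois[t - 1] = BoundaryRoi(t - 1, merged)

    return [rois[t] for t in range(n_frames)]


def rasterize_roi(roi: BoundaryRoi, shape, label: int = 1) -> np.ndarray:
    """Fill an ROI polygon into a label image of the given 2D shape."""
    out = np.zeros(shape, dtype=np.uint8)
    rr, cc = draw_polygon(roi.points[:, 0], roi.points[:, 1], shape)
    out[rr, cc] = label
    return out


def write_rois_csv(rois: list[BoundaryRoi], path) -> None:
    """ROI polygons as CSV rows (timepoint, vertex_index, y, x)."""
    rows = []
    for roi in rois:
        for k, (y, x) in enumerate(roi.points):
            rows.append({"timepoint": roi.timepoint, "vertex_index": k,
                         "y": int(y), "x": int(x)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rois_csv(path) -> list[BoundaryRoi]:
    """Read ROI polygons written by :func:`write_rois_csv`."""
    df = pd.read_csv(Path(path))
    rois = []
    for t, group in df.groupby("timepoint"):
        group = group.sort_values("vertex_index")
        rois.append(BoundaryRoi(int(t), group[["y", "x"]].to_numpy()))
    return rois
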