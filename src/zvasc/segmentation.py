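"""Self-supervised vessel segmentation trained on circulating red blood cells.

Red blood cells circulate strictly inside vessels, so a filtered and
thresholded RBC channel is an inherent proxy for a luminal marker and
supplies training labels without any manual annotation. The pipeline:

1. luminal proxy — Gaussian-filter the RBC channel, Otsu-threshold;
2. training set — candidate voxels near vessels (endothelial
   Otsu-foreground ∪ luminal proxy, dilated), randomly shuffled, first N
   positives (inside the proxy) and first N negatives collected without
   replacement (N = 5000 by default);
3. weights — six standardized endothelial features plus a bias solved
   against the 0/1 labels by SVD (minimum-norm least squares);
4. score — the linear combination of feature maps, one score per voxel;
5. threshold — Triangle algorithm on a 256-bin score histogram;
6. cleanup — morphological opening (erosion then dilation, 6-connected
   cross) removing single-voxel fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .features import ChannelVolume, FeatureStack, compute_feature_stack

__all__ = [
    "BinaryMask",
    "TrainingSet",
    "SegmentationModel",
    "SegmentationConfig",
    "SegmentationStageError",
    "luminal_proxy",
    "sample_training_points",
    "fit_feature_weights",
    "score_volume",
    "triangle_threshold",
    "morphological_cleanup",
    "segment_volume",
]

DEFAULT_N_SAMPLES = 5000
DEFAULT_PROXY_SIGMA = 2.0  # px, Gaussian smoothing before Otsu on the RBC channel
DEFAULT_CANDIDATE_DILATION = 2  # voxels of dilation around the vessel/lumen union
SCORE_HISTOGRAM_BINS = 256


class SegmentationStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names where."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class BinaryMask:
    """A 3D binary mask with voxel spacing metadata."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three strictly positive values")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class TrainingSet:
    """Sampled voxel coordinates with 1 (luminal) / 0 (non-luminal) labels."""

    coordinates: np.ndarray  # (n, 3) integer voxel indices
    labels: np.ndarray  # (n,) in {0, 1}
    n_per_class: int
    shortfall: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.coordinates) != len(self.labels):
            raise ValueError("coordinates and labels must be parallel")

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


@dataclass
class SegmentationModel:
    """Fitted linear voxel classifier: 6 feature weights + bias,
    the training standardization, and the Triangle score threshold."""

    weights: np.ndarray  # shape (7,): 6 feature weights then bias
    feature_means: np.ndarray
    feature_sds: np.ndarray
    score_threshold: float | None = None
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (7,):
            raise ValueError("weights must be 6 feature weights plus a bias")
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64)
        self.feature_sds = np.asarray(self.feature_sds, dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "score_threshold": self.score_threshold,
            "training_summary": self.training_summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationModel":
        return cls(
            np.asarray(d["weights"]),
            np.asarray(d["feature_means"]),
            np.asarray(d["feature_sds"]),
            d.get("score_threshold"),
            d.get("training_summary", {}),
        )


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline."""

    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0
    proxy_sigma: float = DEFAULT_PROXY_SIGMA
    candidate_dilation: int = DEFAULT_CANDIDATE_DILATION
    histogram_bins: int = SCORE_HISTOGRAM_BINS


# ---------------------------------------------------------------------------
# stage 1: luminal proxy
# ---------------------------------------------------------------------------

def luminal_proxy(rbc: ChannelVolume, smoothing_sigma: float = DEFAULT_PROXY_SIGMA) -> BinaryMask:
    """Binary luminal mask from the red-blood-cell channel.

    Gaussian smoothing (``smoothing_sigma`` in pixels) consolidates the
    speckled RBC signal, then an Otsu threshold separates luminal signal
    from background. A flat image has no separable threshold and yields
    an empty mask with a warning.
    """
    if rbc.channel != "rbc":
        raise ValueError(f"expected an rbc channel, got {rbc.channel!r}")
    smoothed = ndimage.gaussian_filter(rbc.intensities, smoothing_sigma)
    if np.ptp(smoothed) == 0:
        warnings.warn("flat RBC channel: no threshold separable, returning empty mask",
                      stacklevel=2)
        return BinaryMask(np.zeros(rbc.shape, dtype=bool), rbc.voxel_spacing)
    thr = threshold_otsu(smoothed)
    return BinaryMask(smoothed > thr, rbc.voxel_spacing)


# ---------------------------------------------------------------------------
# stage 2: training points
# ---------------------------------------------------------------------------

def sample_training_points(
    vessel: ChannelVolume,
    lumen_mask: BinaryMask,
    N: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    candidate_dilation: int = DEFAULT_CANDIDATE_DILATION,
) -> TrainingSet:
    """Sample N luminal and N non-luminal training voxels near vessels.

    Candidate voxels are the union of the endothelial channel's
    Otsu-foreground and the luminal proxy, dilated by
    ``candidate_dilation`` voxels — so negatives are hard examples on and
    around vessel walls rather than trivial background. Candidates are
    uniformly shuffled under ``seed`` and the first N of each class are
    kept, without replacement. If a class runs short, all available
    points are returned and ``shortfall`` is set (never duplicated).
    """
    if vessel.shape != lumen_mask.shape:
        raise ValueError("vessel volume and lumen mask shapes differ")
    if N < 1:
        raise ValueError("N must be >= 1")
    data = vessel.intensities
    if np.ptp(data) == 0:
        vessel_fg = np.zeros(data.shape, dtype=bool)
    else:
        vessel_fg = data > threshold_otsu(data)
    candidates = vessel_fg | lumen_mask.voxels
    if candidate_dilation > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        candidates = ndimage.binary_dilation(
            candidates, structure=structure, iterations=candidate_dilation
        )

    coords = np.argwhere(candidates)
    rng = np.random.default_rng(seed)
    coords = coords[rng.permutation(len(coords))]

    is_pos = lumen_mask.voxels[tuple(coords.T)]
    pos = coords[is_pos][:N]
    neg = coords[~is_pos][:N]
    shortfall = len(pos) < N or len(neg) < N

    coordinates = np.vstack([pos, neg]) if len(pos) + len(neg) else np.empty((0, 3), int)
    labels = np.concatenate([np.ones(len(pos), np.int8), np.zeros(len(neg), np.int8)])
    return TrainingSet(coordinates, labels, N, shortfall=shortfall)


# ---------------------------------------------------------------------------
# stage 3: SVD solve for feature weights
# ---------------------------------------------------------------------------

def fit_feature_weights(features: FeatureStack, training: TrainingSet) -> SegmentationModel:
    """Solve the 6-feature + bias linear model against the 0/1 labels.

    Rows of the design matrix are the z-scored features at the training
    coordinates plus a constant-1 bias column; the weight vector is the
    minimum-norm least-squares solution via SVD pseudo-inverse, i.e. the
    linear scorer whose predictions best match the luminal labels. The
    training standardization and the fit residual ``‖Xw − y‖²`` are
    recorded on the model.
    """
    if len(training.coordinates) == 0:
        raise ValueError("empty training set")
    y = training.labels.astype(np.float64)
    if training.n_positive == 0 or training.n_negative == 0:
        raise ValueError("training set must contain both classes")
    X = features.standardized_at(training.coordinates)
    X = np.hstack([X, np.ones((len(X), 1))])
    weights, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    residual = float(np.sum((X @ weights - y) ** 2))
    return SegmentationModel(
        weights,
        features.means.copy(),
        features.sds.copy(),
        training_summary={
            "n_positive": training.n_positive,
            "n_negative": training.n_negative,
            "shortfall": training.shortfall,
            "fit_residual": residual,
        },
    )


# ---------------------------------------------------------------------------
# stage 4: scoring
# ---------------------------------------------------------------------------

def score_volume(features: FeatureStack, model: SegmentationModel) -> np.ndarray:
    """Per-voxel segmentation score: Σ wᵢ·featureᵢ(z-scored) + bias.

    Uses the standardization stored on the model (the training
    statistics), so a model fitted on one stack scores another
    consistently.
    """
    if features.shape is None:
        raise ValueError("empty feature stack")
    score = np.full(features.shape, model.weights[6], dtype=np.float64)
    for w, fmap, mean, sd in zip(
        model.weights[:6], features.maps(), model.feature_means, model.feature_sds
    ):
        if w != 0.0:
            score += w * ((fmap - mean) / sd)
    return score


# ---------------------------------------------------------------------------
# stage 5: Triangle threshold
# ---------------------------------------------------------------------------

def triangle_threshold(histogram) -> tuple[int, bool]:
    """Triangle-algorithm threshold bin of an intensity histogram.

    A line is drawn from the histogram peak to the far end of the longer
    tail (the last nonzero bin on that side); the threshold is the bin
    maximizing the distance between the histogram and that line. If the
    long tail lies to the left, the histogram is mirrored, processed, and
    the answer mirrored back.

    Returns
    -------
    (bin_index, degenerate)
        ``degenerate`` is True for single-spike histograms, where the
        peak bin itself is returned.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or len(counts) < 1:
        raise ValueError("histogram must be a 1D array of counts")
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(counts)
    if len(nonzero) == 0:
        raise ValueError("histogram is empty")
    if len(nonzero) < 2:
        return int(nonzero[0]), True

    peak = int(np.argmax(counts))
    first, last = nonzero[0], nonzero[-1]
    if peak - first > last - peak:
        # long tail on the left: mirror, solve, mirror back
        idx, degenerate = triangle_threshold(counts[::-1])
        return len(counts) - 1 - idx, degenerate

    if last == peak:
        return peak, True
    # vertical distance to the peak→tail-end line; ranking is equivalent to
    # the perpendicular distance since the line is fixed
    bins = np.arange(peak, last + 1, dtype=np.float64)
    line = counts[peak] + (counts[last] - counts[peak]) * (bins - peak) / (last - peak)
    distances = line - counts[peak : last + 1]
    return peak + int(np.argmax(distances)), False


def _threshold_scores(score: np.ndarray, n_bins: int = SCORE_HISTOGRAM_BINS):
    """Binarize a score image with the Triangle threshold on an n-bin histogram."""
    lo, hi = float(score.min()), float(score.max())
    if lo == hi:
        return np.zeros(score.shape, dtype=bool), lo
    counts, edges = np.histogram(score, bins=n_bins, range=(lo, hi))
    bin_idx, _ = triangle_threshold(counts)
    thr = edges[bin_idx + 1]  # right edge: foreground strictly above the threshold bin
    return score > thr, float(thr)


# ---------------------------------------------------------------------------
# stage 6: morphological cleanup
# ---------------------------------------------------------------------------

def morphological_cleanup(mask: BinaryMask) -> BinaryMask:
    """Morphological opening (erosion then dilation) with a 6-connected
    3×3×3 cross, removing single-voxel fragments while preserving solid
    structures."""
    structure = ndimage.generate_binary_structure(3, 1)
    opened = ndimage.binary_opening(mask.voxels, structure=structure)
    return BinaryMask(opened, mask.voxel_spacing)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def segment_volume(
    vessel: ChannelVolume,
    rbc: ChannelVolume,
    config: SegmentationConfig | None = None,
    model: SegmentationModel | None = None,
) -> tuple[BinaryMask, SegmentationModel]:
    """Segment a two-channel stack end to end.

    Runs luminal proxy → training sampling → feature extraction → SVD
    weight solve → scoring → Triangle threshold → morphological opening,
    and returns the cleaned mask together with the model used. Passing a
    previously fitted ``model`` skips the self-supervision stages and
    re-uses its weights and standardization (per-stack refitting is the
    default). Stage failures raise :class:`SegmentationStageError`
    naming the stage.
    """
    config = config or SegmentationConfig()
    if vessel.shape != rbc.shape:
        raise SegmentationStageError("input", "channel shapes differ")

    try:
        feats = compute_feature_stack(vessel)
    except ValueError as e:
        raise SegmentationStageError("features", str(e)) from e

    if model is None:
        try:
            lumen = luminal_proxy(rbc, config.proxy_sigma)
        except ValueError as e:
            raise SegmentationStageError("luminal_proxy", str(e)) from e
        try:
            training = sample_training_points(
                vessel, lumen, config.n_samples, config.seed, config.candidate_dilation
            )
            if training.n_positive == 0:
                raise ValueError("no positive (luminal) training points; is the "
                                 "RBC channel empty?")
            model = fit_feature_weights(feats, training)
        except ValueError as e:
            raise SegmentationStageError("training", str(e)) from e

    score = score_volume(feats, model)
    binary, thr = _threshold_scores(score, config.histogram_bins)
    model.score_threshold = thr
    mask = morphological_cleanup(BinaryMask(binary, vessel.voxel_spacing))
    return mask, model


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
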