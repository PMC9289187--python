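"""The 4-step 3D segmentation pipeline for islet-microtissue stacks.

1. Spheroid detection on the DAPI channel by Otsu thresholding.
2. Nuclear segmentation in DAPI by dynamic (local) thresholding inside
   the spheroid, with a distance-transform-seeded watershed to split
   touching nuclei.
3. Marker segmentation (NKX6.1, EdU) by the same dynamic-threshold rule,
   with per-stack NKX6.1 intensity truncation beforehand so all wells sit
   in a similar intensity range.
4. Per-nucleus marker scoring: a nucleus is marker-positive when the
   fraction of its voxels above the dynamic threshold exceeds a
   configured fraction.

"Dynamic thresholding" here is local-mean-plus-offset: a voxel is
foreground when its (smoothed) intensity exceeds the mean over a local
window of physical size ``window_um`` by ``offset_k`` robust standard
deviations, the robust SD being estimated from the in-mask voxels
(median absolute deviation scaled to the normal). The window is
converted to voxels per axis, respecting anisotropy. Everything is
deterministic: identical stack + config give identical label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from isletmt.errors import ConfigError, DegenerateHistogramError, NoSpheroidError
from isletmt.grid import VoxelGrid

_MAD_TO_SD = 1.4826  # normal-consistency factor for the median absolute deviation


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SpheroidConfig:
    """Spheroid-detection parameters (step 1)."""

    n_bins: int = 256                  # Otsu histogram bins
    smooth_sigma_um: float = 1.5       # pre-smoothing before Otsu
    closing_radius_um: float = 4.0     # morphological closing radius
    min_volume_um3: float = 10_000.0   # below this: "no spheroid detected"
    #: the Otsu threshold must exceed the stack median by this many robust
    #: SDs, otherwise the "foreground" is just the upper half of the noise
    min_contrast_k: float = 3.0


@dataclass
class SegmentationConfig:
    """Dynamic-threshold nuclear/marker segmentation parameters (steps 2-4)."""

    smooth_sigma_um: float = 1.0       # Gaussian pre-smoothing, physical sigma
    window_um: float = 15.0            # local-mean window (physical, per axis)
    offset_k: float = 3.0              # threshold offset in robust SDs
    min_volume_um3: float = 30.0       # nucleus volume gate, lower
    max_volume_um3: float = 1500.0     # nucleus volume gate, upper
    min_seed_separation_um: float = 4.0  # watershed seed spacing (~nucleus radius)
    positive_fraction: float = 0.5     # voxel fraction for marker positivity


@dataclass
class TruncationConfig:
    """NKX6.1 intensity truncation percentiles (within the spheroid mask)."""

    lower_pct: float = 1.0
    upper_pct: float = 99.5


@dataclass
class PipelineConfig:
    spheroid: SpheroidConfig = field(default_factory=SpheroidConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    truncation: TruncationConfig = field(default_factory=TruncationConfig)
    #: channel key -> page index or channel name in the input stack
    channels: dict = field(default_factory=lambda: {"dapi": 0, "nkx6_1": 1, "edu": 2})


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class SpheroidMask:
    """Binary spheroid region congruent with its source grid."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    threshold_used: float

    @property
    def volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return float(np.count_nonzero(self.mask)) * dz * dy * dx


@dataclass
class NucleusLabelMap:
    """Labeled nuclei: 0 = background, k >= 1 = nucleus k (consecutive)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    n_labels: int


# --------------------------------------------------------------------------
# step 1: Otsu + spheroid detection
# --------------------------------------------------------------------------

def otsu_threshold(grid: VoxelGrid | np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance of the intensity histogram.

    The histogram spans [min, max] with ``n_bins`` equal bins; candidate
    thresholds are the interior bin edges, a voxel belonging to the upper
    class when its intensity is >= the edge. Ties break to the lowest
    qualifying threshold.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (fewer than 2 distinct values).
    """
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    lo, hi = float(np.min(data)), float(np.max(data))
    if lo == hi:
        raise DegenerateHistogramError(
            f"constant image (all voxels = {lo}): no threshold exists")
    counts, edges = np.histogram(data.ravel(), bins=n_bins, range=(lo, hi))

    # Between-class variance is invariant (up to a positive affine factor)
    # under affine maps of the bin centers, so weights 2i+1 stand in for
    # the real centers and everything stays in exact integer arithmetic:
    # sigma_B^2(k) ∝ (cm0*w1 - cm1*w0)^2 / (w0*w1). Exact comparison makes
    # the maximizer reproducible against an exhaustive search even when
    # adjacent splits are nearly tied.
    counts_int = [int(c) for c in counts]
    weights = [(2 * i + 1) * c for i, c in enumerate(counts_int)]
    total_w = sum(counts_int)
    total_cm = sum(weights)

    best_k, best_num, best_den = None, -1, 1
    w0 = cm0 = 0
    for k in range(1, n_bins):
        w0 += counts_int[k - 1]
        cm0 += weights[k - 1]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        a = cm0 * w1 - (total_cm - cm0) * w0
        num, den = a * a, w0 * w1
        if num * best_den > best_num * den:  # strict: ties keep lowest edge
            best_k, best_num, best_den = k, num, den
    return float(edges[best_k])


def _window_voxels(window_um: float, voxel_size: tuple[float, float, float],
                   minimum: int = 1) -> tuple[int, int, int]:
    sizes = tuple(max(minimum, int(round(window_um / v))) for v in voxel_size)
    return sizes


def _ellipsoid_footprint(radius_um: float,
                         voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Anisotropy-aware ellipsoid structuring element of physical radius."""
    half = [max(1, int(round(radius_um / v))) for v in voxel_size]
    zz, yy, xx = np.ogrid[-half[0]:half[0] + 1, -half[1]:half[1] + 1,
                          -half[2]:half[2] + 1]
    return ((zz * voxel_size[0]) ** 2 + (yy * voxel_size[1]) ** 2
            + (xx * voxel_size[2]) ** 2) <= radius_um ** 2


def detect_spheroid(dapi: VoxelGrid, config: SpheroidConfig | None = None) -> SpheroidMask:
    """Detect the whole-spheroid region from the DAPI channel.

    Gaussian pre-smoothing (so the tissue region, not individual nuclei,
    dominates the histogram) -> Otsu threshold -> binary mask ->
    morphological closing (physical radius, scaled per axis by voxel
    size) -> largest connected component -> per-plane hole filling. The
    result is a single connected component.

    Raises
    ------
    NoSpheroidError
        If the detected foreground is below ``min_volume_um3``.
    DegenerateHistogramError
        If the DAPI volume is constant.
    """
    config = config or SpheroidConfig()
    data = dapi.data.astype(np.float64)
    if config.smooth_sigma_um > 0:
        sigma = tuple(config.smooth_sigma_um / v for v in dapi.voxel_size)
        data = ndimage.gaussian_filter(data, sigma=sigma)
    thr = otsu_threshold(data, n_bins=config.n_bins)
    floor = float(np.median(data)) + config.min_contrast_k * _robust_sd(data)
    if thr < floor:
        raise NoSpheroidError(
            f"no spheroid detected: Otsu threshold {thr:.2f} is within noise "
            f"of the stack median (floor {floor:.2f})")
    mask = data >= thr

    if config.closing_radius_um > 0:
        footprint = _ellipsoid_footprint(config.closing_radius_um, dapi.voxel_size)
        mask = ndimage.binary_closing(mask, structure=footprint)

    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoSpheroidError("no foreground voxels above the Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels,
                               index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest

    # fill internal holes plane by plane (the spheroid interior can be dim)
    for z in range(mask.shape[0]):
        mask[z] = ndimage.binary_fill_holes(mask[z])

    out = SpheroidMask(mask=mask, voxel_size=dapi.voxel_size, threshold_used=thr)
    if out.volume_um3 < config.min_volume_um3:
        raise NoSpheroidError(
            f"no spheroid detected: foreground volume {out.volume_um3:.0f} µm³ "
            f"< minimum {config.min_volume_um3:.0f} µm³")
    return out


# --------------------------------------------------------------------------
# dynamic thresholding (shared by steps 2-4)
# --------------------------------------------------------------------------

def _robust_sd(values: np.ndarray) -> float:
    """Normal-consistent median-absolute-deviation scale estimate."""
    med = np.median(values)
    return float(_MAD_TO_SD * np.median(np.abs(values - med)))


def dynamic_threshold_mask(grid: VoxelGrid, region: np.ndarray,
                           config: SegmentationConfig) -> np.ndarray:
    """Foreground voxels by local-mean-plus-offset thresholding in ``region``.

    A voxel is foreground when its smoothed intensity exceeds the local
    mean over the physical window by ``offset_k`` times the robust SD of
    the in-region smoothed intensities. The window must span at least 3
    voxels along every axis.
    """
    window = _window_voxels(config.window_um, grid.voxel_size)
    if any(w < 3 for w in window):
        raise ConfigError(
            f"local-threshold window {config.window_um} µm spans {window} voxels "
            f"at voxel size {grid.voxel_size}; need >= 3 along every axis")
    if not region.any():
        return np.zeros(grid.shape, dtype=bool)
    sigma = tuple(config.smooth_sigma_um / v for v in grid.voxel_size)
    smoothed = ndimage.gaussian_filter(grid.data.astype(np.float64), sigma=sigma)
    # mask-normalized local mean: out-of-region voxels (e.g. the dark
    # background outside the spheroid) must not drag the window mean down
    weight = region.astype(np.float64)
    local_sum = ndimage.uniform_filter(smoothed * weight, size=window)
    local_n = ndimage.uniform_filter(weight, size=window)
    local_mean = np.divide(local_sum, local_n, out=np.zeros_like(local_sum),
                           where=local_n > 0)
    residual = smoothed - local_mean
    sd = _robust_sd(residual[region])
    return (residual > config.offset_k * sd) & region


# --------------------------------------------------------------------------
# step 2: nuclear segmentation
# --------------------------------------------------------------------------

def segment_nuclei(dapi: VoxelGrid, spheroid: SpheroidMask,
                   config: SegmentationConfig | None = None) -> NucleusLabelMap:
    """Segment and label individual nuclei in the DAPI channel.

    Dynamic thresholding inside the spheroid mask, then a marker-controlled
    watershed on the (anisotropy-aware) Euclidean distance transform to
    split touching nuclei, then a physical volume gate. Labels are
    consecutive from 1. An empty spheroid mask yields a zero-label map.
    """
    config = config or SegmentationConfig()
    if dapi.data.shape != spheroid.mask.shape:
        raise ValueError(
            f"DAPI shape {dapi.data.shape} != mask shape {spheroid.mask.shape}")
    if not spheroid.mask.any():
        return NucleusLabelMap(labels=np.zeros(dapi.shape, dtype=np.int32),
                               voxel_size=dapi.voxel_size, n_labels=0)

    fg = dynamic_threshold_mask(dapi, spheroid.mask, config)
    if not fg.any():
        return NucleusLabelMap(labels=np.zeros(dapi.shape, dtype=np.int32),
                               voxel_size=dapi.voxel_size, n_labels=0)

    distance = ndimage.distance_transform_edt(fg, sampling=dapi.voxel_size)
    footprint = _ellipsoid_footprint(config.min_seed_separation_um, dapi.voxel_size)
    peaks = peak_local_max(distance, footprint=footprint, labels=fg,
                           exclude_border=False)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndimage.label(markers > 0)  # merge seeds closer than 1 voxel
    labels = watershed(-distance, markers=markers, mask=fg)

    return _gate_and_relabel(labels, dapi.voxel_size, config)


def _gate_and_relabel(labels: np.ndarray, voxel_size, config: SegmentationConfig
                      ) -> NucleusLabelMap:
    """Drop labels outside the physical volume gate, relabel consecutively."""
    voxvol = float(np.prod(voxel_size))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    volumes = counts * voxvol
    keep = ids[(volumes >= config.min_volume_um3) & (volumes <= config.max_volume_um3)]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    out = lut[labels]
    return NucleusLabelMap(labels=out, voxel_size=tuple(voxel_size),
                           n_labels=int(len(keep)))


# --------------------------------------------------------------------------
# NKX6.1 truncation
# --------------------------------------------------------------------------

def truncate_intensities(grid: VoxelGrid, lower_pct: float, upper_pct: float,
                         reference_region: SpheroidMask) -> VoxelGrid:
    """Clip intensities to in-mask percentile bounds (idempotent).

    Percentiles are computed over the voxels inside ``reference_region``
    using order statistics (lower bound with the ``lower``, upper bound
    with the ``higher`` interpolation rule, which makes a second
    application a no-op); the whole volume is then clipped to those
    bounds. This brings stacks of different overall staining intensity
    into a similar range before dynamic thresholding.
    """
    if not (0.0 <= lower_pct < upper_pct <= 100.0):
        raise ValueError(
            f"need 0 <= lower_pct < upper_pct <= 100, got ({lower_pct}, {upper_pct})")
    ref = grid.data[reference_region.mask]
    if ref.size == 0:
        raise ValueError("reference region is empty")
    lo = float(np.quantile(ref, lower_pct / 100.0, method="lower"))
    hi = float(np.quantile(ref, upper_pct / 100.0, method="higher"))
    return grid.with_data(np.clip(grid.data, lo, hi))


# --------------------------------------------------------------------------
# steps 3-4: marker scoring
# --------------------------------------------------------------------------

def score_markers(marker: VoxelGrid, nuclei: NucleusLabelMap,
                  spheroid: SpheroidMask,
                  config: SegmentationConfig | None = None
                  ) -> list[tuple[int, float, bool]]:
    """Per-nucleus marker mean intensity and positivity flag.

    The marker channel is segmented with the same dynamic-threshold rule
    as the nuclei (inside the spheroid mask); a nucleus is positive when
    the fraction of its voxels above threshold exceeds
    ``positive_fraction``. Returns ``(label, mean_intensity, positive)``
    for labels 1..n. The rule is contrast-based, not absolute: rescaling
    the whole channel leaves the partition unchanged.
    """
    config = config or SegmentationConfig()
    if marker.data.shape != nuclei.labels.shape:
        raise ValueError(
            f"marker shape {marker.data.shape} != label-map shape {nuclei.labels.shape}")
    if marker.data.shape != spheroid.mask.shape:
        raise ValueError(
            f"marker shape {marker.data.shape} != mask shape {spheroid.mask.shape}")
    if nuclei.n_labels == 0:
        return []
    index = np.arange(1, nuclei.n_labels + 1)
    means = ndimage.mean(marker.data, labels=nuclei.labels, index=index)
    fg = dynamic_threshold_mask(marker, spheroid.mask, config)
    fractions = ndimage.mean(fg.astype(np.float64), labels=nuclei.labels, index=index)
    return [(int(lbl), float(m), bool(f > config.positive_fraction))
            for lbl, m, f in zip(index, means, fractions)]
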