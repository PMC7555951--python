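"""Per-frame focus segmentation with an adaptive, calibrated threshold.

The segmentation stage follows the classic live-cell focus-counting recipe:
maximum-intensity projection, nucleus segmentation, rigid-body stack
stabilization, and an adaptive per-frame intensity threshold. The threshold is
calibrated once on the first frame from a manually chosen lower threshold
``L``::

    factor      = (L - mean_0) / sd_0
    threshold_t = mean_t + factor * sd_t

where ``mean_t`` / ``sd_t`` are the mean and sample standard deviation of the
nuclear pixels of frame ``t``. The factor is held constant for all frames of
one cell, so the cutoff tracks global intensity changes (e.g. bleaching).
Touching foci are separated by watershed and measured (area, mean intensity,
intensity-weighted center of mass).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, transform
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.segmentation import clear_border, watershed

__all__ = [
    "FrameStats",
    "ThresholdModel",
    "Focus",
    "max_project",
    "segment_nuclei",
    "register_stack",
    "compute_frame_stats",
    "calibrate_threshold_factor",
    "frame_threshold",
    "segment_foci",
    "measure_foci",
]


@dataclass(frozen=True)
class FrameStats:
    """Mean and sample SD of nuclear pixel intensity in one frame."""

    frame_index: int
    mean_intensity: float
    sd_intensity: float


@dataclass(frozen=True)
class ThresholdModel:
    """Calibrated adaptive-threshold model of one cell.

    ``factor`` is dimensionless; applying the model to the calibration frame's
    own statistics returns ``manual_lower_threshold`` exactly.
    """

    factor: float
    manual_lower_threshold: float
    upper_threshold: float = 255.0


@dataclass(frozen=True)
class Focus:
    """One segmented focus in one frame.

    ``com`` is the (x, y) center of mass in µm; ``area`` in µm²;
    ``total_intensity = mean_intensity * area``.
    """

    frame_index: int
    label: int
    com: tuple[float, float]
    area: float
    mean_intensity: float
    total_intensity: float


def max_project(z_stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the leading (z) axis."""
    z_stack = np.asarray(z_stack)
    if z_stack.ndim != 3 or z_stack.shape[0] < 1:
        raise ValueError("z_stack must be a 3D array with at least one plane")
    return z_stack.max(axis=0)


def segment_nuclei(
    image: np.ndarray,
    min_area: int = 200,
    fill_holes: bool = True,
    exclude_border: bool = True,
) -> np.ndarray:
    """Segment nuclei by global Otsu threshold.

    Connected components of the thresholded image are hole-filled, components
    touching the image border or smaller than ``min_area`` pixels are
    discarded, and the survivors are relabeled 1..n. A blank (constant) image
    yields zero nuclei.

    The automatic threshold is the lowest cut of a three-class Otsu
    (background / nucleoplasm / bright foci), so bright sub-nuclear spots do
    not drag the nuclear outline inward; images without a third class fall
    back to ordinary two-class Otsu.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    try:
        th = filters.threshold_multiotsu(image, classes=3)[0]
    except ValueError:  # fewer than 3 distinguishable classes
        th = filters.threshold_otsu(image)
    binary = image > th
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)
    if exclude_border:
        binary = clear_border(binary)
    if min_area > 0:
        # drop components with fewer than min_area pixels
        binary = morphology.remove_small_objects(binary, max_size=min_area - 1)
    labels, _ = ndi.label(binary)
    return labels.astype(np.int32)


def _estimate_rotation(ref: np.ndarray, mov: np.ndarray, angular_bins: int = 720,
                       upsample: int = 20) -> float:
    """Rotation of ``mov`` relative to ``ref`` (deg) via log-free polar FFT.

    The FFT magnitude is translation invariant, so the angular shift of its
    polar transform isolates rotation. The magnitude's 180° symmetry limits
    the estimate to (-90°, 90°]; fine for frame-to-frame nuclear motion.
    """
    win = filters.window("hann", ref.shape)
    f_ref = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(ref * win))))
    f_mov = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(mov * win))))
    # suppress the DC neighbourhood, which is rotation invariant and would
    # otherwise dominate the angular correlation
    h, w = f_ref.shape
    yy, xx = np.mgrid[0:h, 0:w]
    keep = np.hypot(yy - h / 2, xx - w / 2) >= 4
    f_ref = f_ref * keep
    f_mov = f_mov * keep
    radius = min(ref.shape) // 2
    p_ref = transform.warp_polar(f_ref, radius=radius, output_shape=(angular_bins, radius))
    p_mov = transform.warp_polar(f_mov, radius=radius, output_shape=(angular_bins, radius))
    shift, _, _ = phase_cross_correlation(
        p_ref, p_mov, upsample_factor=upsample, normalization=None
    )
    angle = shift[0] * 360.0 / angular_bins
    angle = (angle + 90.0) % 180.0 - 90.0
    return float(angle)


def register_stack(
    stack: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    estimate_rotation: bool = True,
    upsample: int = 20,
) -> tuple[np.ndarray, list[tuple[float, tuple[float, float]]]]:
    """Stabilize a time-lapse by rigid-body alignment of every frame to frame 0.

    Rotation is estimated from the polar transform of the FFT magnitude,
    translation by phase cross-correlation after de-rotation. Out-of-frame
    pixels are filled with the frame's median (background) intensity.

    Returns the registered stack and, per frame, the applied
    ``(rotation_deg, (shift_y, shift_x))`` mapping frame -> frame 0.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must have at least 2 frames")
    ref = stack[0]
    out = np.empty_like(stack)
    out[0] = ref
    transforms: list[tuple[float, tuple[float, float]]] = [(0.0, (0.0, 0.0))]
    if np.ptp(ref) == 0:
        warnings.warn("reference frame is constant; returning stack unchanged")
        return stack.copy(), [(0.0, (0.0, 0.0))] * stack.shape[0]
    for t in range(1, stack.shape[0]):
        frame = stack[t]
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {t} is constant; left unregistered")
            out[t] = frame
            transforms.append((0.0, (0.0, 0.0)))
            continue
        bg = float(np.median(frame))
        angle = _estimate_rotation(ref, frame, upsample=upsample) if estimate_rotation else 0.0
        derot = (
            transform.rotate(frame, -angle, preserve_range=True, cval=bg, order=1)
            if abs(angle) > 1e-6
            else frame
        )
        shift, _, _ = phase_cross_correlation(ref, derot, upsample_factor=upsample,
                                              normalization=None)
        aligned = ndi.shift(derot, shift, order=1, cval=bg)
        out[t] = aligned
        transforms.append((float(angle), (float(shift[0]), float(shift[1]))))
    return out, transforms


def compute_frame_stats(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    frame_index: int = 0,
    ddof: int = 1,
) -> FrameStats:
    """Mean and sample standard deviation of the masked (nuclear) pixels.

    The SD uses the n−1 denominator by default (``ddof=1``); a mask covering
    fewer than 2 pixels is rejected because the SD is undefined.
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size < 2:
        raise ValueError(
            f"frame {frame_index}: nucleus mask covers {vals.size} pixel(s); need >= 2"
        )
    return FrameStats(
        frame_index=frame_index,
        mean_intensity=float(vals.mean()),
        sd_intensity=float(vals.std(ddof=ddof)),
    )


def calibrate_threshold_factor(
    manual_lower_threshold: float,
    stats0: FrameStats,
    upper_threshold: float = 255.0,
) -> ThresholdModel:
    """Convert a manually chosen first-frame threshold into a reusable factor.

    ``factor = (L - mean_0) / sd_0``; held constant for every frame of the
    same cell.
    """
    if stats0.sd_intensity <= 0:
        raise ValueError(
            f"frame {stats0.frame_index}: zero intensity SD, threshold factor undefined"
        )
    factor = (manual_lower_threshold - stats0.mean_intensity) / stats0.sd_intensity
    return ThresholdModel(
        factor=factor,
        manual_lower_threshold=manual_lower_threshold,
        upper_threshold=upper_threshold,
    )


def frame_threshold(stats_t: FrameStats, model: ThresholdModel) -> float:
    """Per-frame adaptive threshold: ``mean_t + factor * sd_t``."""
    return stats_t.mean_intensity + model.factor * stats_t.sd_intensity


def _split_touching(
    binary: np.ndarray,
    peak_surface: np.ndarray,
    min_peak_distance: int,
) -> np.ndarray:
    """Watershed-split a binary mask using local maxima of ``peak_surface``."""
    blob_labels, n = ndi.label(binary)
    if n == 0:
        return blob_labels
    coords = peak_local_max(
        peak_surface,
        labels=blob_labels,
        min_distance=min_peak_distance,
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # any blob that got no marker (flat plateau) keeps a single seed
    seeded = set(np.unique(blob_labels[markers > 0]))
    for lab in range(1, n + 1):
        if lab not in seeded:
            rr, cc = np.nonzero(blob_labels == lab)
            markers[rr[0], cc[0]] = markers.max() + 1
    return watershed(-peak_surface, markers, mask=binary)


def segment_foci(
    image: np.ndarray,
    threshold: float,
    upper_threshold: float = 255.0,
    smoothing_sigma: float = 1.0,
    min_area: int = 4,
    mask: np.ndarray | None = None,
    min_peak_distance: int = 2,
    split_method: str = "intensity",
) -> np.ndarray:
    """Threshold a frame between ``[threshold, upper_threshold]`` and split
    touching foci by watershed.

    ``split_method`` chooses the watershed surface: ``"intensity"`` (default)
    seeds at local maxima of the σ-smoothed image, which separates overlapping
    diffraction-limited spots whose merged mask has no waist; ``"distance"``
    uses the Euclidean distance transform of the binary mask (the classic
    binary watershed). Blobs below ``min_area`` pixels are dropped and the
    result relabeled 1..n.
    """
    image = np.asarray(image, dtype=float)
    binary = (image >= threshold) & (image <= upper_threshold)
    if mask is not None:
        binary &= np.asarray(mask, dtype=bool)
    if not binary.any():
        return np.zeros(image.shape, dtype=np.int32)
    if split_method == "intensity":
        surface = ndi.gaussian_filter(image, smoothing_sigma) if smoothing_sigma > 0 else image
    elif split_method == "distance":
        surface = ndi.distance_transform_edt(binary)
    else:
        raise ValueError("split_method must be 'intensity' or 'distance'")
    labels = _split_touching(binary, surface, min_peak_distance)
    if min_area > 0:
        sizes = np.bincount(labels.ravel())
        kill = np.nonzero(sizes < min_area)[0]
        labels[np.isin(labels, kill[kill > 0])] = 0
    # relabel the watershed output (not connectivity) so splits survive
    relabeled = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        relabeled[labels == old] = new
    return relabeled


def measure_foci(
    labeled: np.ndarray,
    image: np.ndarray,
    pixel_size: float,
    frame_index: int = 0,
    com_mode: str = "weighted",
) -> list[Focus]:
    """Measure area, mean intensity and center of mass of each labeled focus.

    Areas are reported in µm² (pixel count × pixel_size²) and the center of
    mass in µm, intensity weighted by default (``com_mode="geometric"`` uses
    the unweighted centroid). Pixel (0, 0) has its center at (0, 0) µm.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if com_mode not in ("weighted", "geometric"):
        raise ValueError("com_mode must be 'weighted' or 'geometric'")
    labeled = np.asarray(labeled)
    image = np.asarray(image, dtype=float)
    if labeled.shape != image.shape:
        raise ValueError("labeled map and image must have the same shape")
    foci: list[Focus] = []
    for prop in measure.regionprops(labeled, intensity_image=image):
        if com_mode == "weighted":
            row, col = prop.centroid_weighted
            if math.isnan(row):  # all-zero intensities in the region
                row, col = prop.centroid
        else:
            row, col = prop.centroid
        area = prop.area * pixel_size**2
        mean = float(prop.intensity_mean)
        foci.append(
            Focus(
                frame_index=frame_index,
                label=int(prop.label),
                com=(float(col) * pixel_size, float(row) * pixel_size),
                area=float(area),
                mean_intensity=mean,
                total_intensity=mean * float(area),
            )
        )
    return foci
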