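"""TMRM confocal image quantification.

The pipeline quantifies mitochondrial membrane potential from
single-channel grayscale fluorescence images of TMRM-stained cells or
isolated mitochondria:

1. pixel-wise adaptive (Wiener) low-pass filtering removes background
   noise while keeping structure;
2. Sobel gradient magnitude plus an automatic threshold outlines objects;
3. binary morphology (dilate, fill holes, erode, remove small objects)
   turns the outlines into solid segmented regions;
4. per-region mean intensities are computed on the filtered image;
5. the "bright" (hyperpolarised) area is the segmented area at or above
   half of the maximum filtered intensity, and the bright ratio is bright
   area over segmented area;
6. the response to the uncoupler FCCP is the percentage drop in mean
   fluorescence, ``100 * (f_before - f_after) / f_before``.

Intensities are handled as real numbers in native (arbitrary
fluorescence) units; no rescaling to [0, 1] is performed.  Coordinates
are 0-based ``(row, column)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphology import (
    FG_STRUCTURE_8,
    morph_dilate,
    morph_erode,
    morph_fill_holes,
    morph_remove_small,
    structuring_element,
)

__all__ = [
    "as_intensity_image",
    "adaptive_wiener",
    "gradient_magnitude",
    "auto_threshold",
    "SegmentationConfig",
    "SegmentationResult",
    "segment_mitochondria",
    "bright_area_ratio",
    "FccpResponse",
    "fccp_response",
    "fccp_response_from_images",
]

# MATLAB-convention 3x3 Sobel kernels (correlation), unnormalised: a unit
# vertical step of height h yields gradient magnitude 4h at the edge.
_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


def as_intensity_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D non-negative finite float64 intensity image.

    Images must be at least 3x3 so that the 3x3 gradient kernels and the
    smallest filter windows are defined.
    """
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"intensity image must be 2-D, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"intensity image must be at least 3x3, got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("intensity image contains non-finite values")
    if img.min() < 0:
        raise ValueError("intensity image contains negative values")
    return img


def adaptive_wiener(
    img: np.ndarray,
    window: tuple[int, int] = (5, 5),
    border_mode: str = "reflect",
) -> np.ndarray:
    """Pixel-wise adaptive (Wiener) low-pass filter.

    For each pixel, with local mean ``m`` and local variance ``v`` over the
    window and a global noise estimate ``nu`` (the mean of all local
    variances), the output is::

        m + max(v - nu, 0) / max(v, nu) * (x - m)

    Flat regions (``v <= nu``) collapse to the local mean; structured
    regions (``v >> nu``) are passed through nearly unchanged.  Output is
    clamped at 0 so it remains a valid intensity image.

    Parameters
    ----------
    img:
        2-D intensity image.
    window:
        Odd (rows, cols) neighbourhood size; default 5x5.
    border_mode:
        Padding policy for local statistics (any :mod:`scipy.ndimage` mode).
    """
    img = as_intensity_image(img)
    wr, wc = int(window[0]), int(window[1])
    if wr % 2 == 0 or wc % 2 == 0:
        raise ValueError(f"window dimensions must be odd, got {window}")
    if wr < 3 or wc < 3:
        raise ValueError(f"window dimensions must be >= 3, got {window}")
    if wr > img.shape[0] or wc > img.shape[1]:
        raise ValueError(
            f"window {window} does not fit in image of shape {img.shape}"
        )
    local_mean = ndimage.uniform_filter(img, size=(wr, wc), mode=border_mode)
    local_sq = ndimage.uniform_filter(img * img, size=(wr, wc), mode=border_mode)
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    noise = local_var.mean()
    gain_num = np.maximum(local_var - noise, 0.0)
    gain_den = np.maximum(local_var, noise)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(gain_den > 0.0, gain_num / gain_den, 0.0)
    out = local_mean + gain * (img - local_mean)
    return np.clip(out, 0.0, None)


def gradient_magnitude(img: np.ndarray, border_mode: str = "reflect") -> np.ndarray:
    """Sobel gradient magnitude ``sqrt(gx**2 + gy**2)`` with 3x3 kernels."""
    img = as_intensity_image(img)
    gx = ndimage.correlate(img, _SOBEL_X, mode=border_mode)
    gy = ndimage.correlate(img, _SOBEL_Y, mode=border_mode)
    return np.hypot(gx, gy)


def auto_threshold(grad: np.ndarray, scale: float = 4.0) -> float:
    """Automatic edge threshold: ``scale`` times the mean gradient magnitude.

    Returns 0.0 for an all-zero gradient (no edges anywhere).
    """
    grad = np.asarray(grad, dtype=np.float64)
    if grad.size == 0:
        raise ValueError("gradient image has no pixels")
    if scale <= 0:
        raise ValueError(f"threshold scale must be positive, got {scale}")
    return float(scale * grad.mean())


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    Defaults follow the classical gradient-outline recipe: a 5x5 Wiener
    window, threshold at 4x the mean Sobel magnitude, gap closing with
    orthogonal length-3 line elements, diamond erosion, and removal of
    objects below 2 pixels.  The default erosion radius is 3: the Sobel
    response of a step edge extends about two pixels beyond the object
    boundary and the dilation adds one more, so a radius-3 erosion
    returns the filled outline to the object's own footprint.  With a
    single radius-1 erosion the segmented area carries a bright-diluting
    boundary ring (region means drop by tens of percent on sharp test
    objects).
    """

    wiener_window: tuple[int, int] = (5, 5)
    gradient_threshold_scale: float = 4.0
    dilation_element: str = "lines"
    dilation_radius: int = 1
    erosion_element: str = "diamond"
    erosion_radius: int = 3
    min_object_px: int = 2
    connectivity: int = 8
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        wr, wc = self.wiener_window
        if wr % 2 == 0 or wc % 2 == 0 or wr < 3 or wc < 3:
            raise ValueError(f"wiener_window must be odd and >= 3, got {self.wiener_window}")
        if self.gradient_threshold_scale <= 0:
            raise ValueError("gradient_threshold_scale must be positive")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        # fail early on unknown element names
        structuring_element(self.dilation_element, self.dilation_radius)
        structuring_element(self.erosion_element, self.erosion_radius)

    @property
    def label_structure(self) -> np.ndarray:
        if self.connectivity == 8:
            return FG_STRUCTURE_8
        return ndimage.generate_binary_structure(2, 1)


@dataclass
class SegmentationResult:
    """Labelled segmentation with region and brightness statistics.

    ``labels`` uses 0 for background and consecutive ids ``1..K`` for the
    regions, sorted by descending area.  ``bright_ratio`` is ``None`` when
    nothing was segmented (flagged rather than silently NaN).
    """

    labels: np.ndarray
    region_means: list[tuple[int, float]]
    region_areas: list[tuple[int, int]]
    segmented_area_px: int
    bright_area_px: int
    bright_ratio: float | None
    threshold: float
    filtered: np.ndarray = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.region_means)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def segment_mitochondria(img: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full segmentation pipeline on one intensity image.

    Stage order is fixed: adaptive Wiener filter, Sobel gradient,
    automatic threshold, binarisation, dilation, hole filling, erosion,
    small-object removal, connected-component labelling, then per-region
    statistics on the *filtered* image.
    """
    cfg = cfg or SegmentationConfig()
    img = as_intensity_image(img)
    filtered = adaptive_wiener(img, cfg.wiener_window, cfg.border_mode)
    grad = gradient_magnitude(filtered, cfg.border_mode)
    thr = auto_threshold(grad, cfg.gradient_threshold_scale)
    mask = grad > thr
    if mask.any():
        mask = morph_dilate(mask, structuring_element(cfg.dilation_element, cfg.dilation_radius))
        mask = morph_fill_holes(mask)
        mask = morph_erode(mask, structuring_element(cfg.erosion_element, cfg.erosion_radius))
        mask = morph_remove_small(mask, cfg.min_object_px)

    raw_labels, n_raw = ndimage.label(mask, structure=cfg.label_structure)
    if n_raw == 0:
        return SegmentationResult(
            labels=np.zeros(img.shape, dtype=np.int32),
            region_means=[],
            region_areas=[],
            segmented_area_px=0,
            bright_area_px=0,
            bright_ratio=None,
            threshold=thr,
            filtered=filtered,
        )

    ids = np.arange(1, n_raw + 1)
    areas = ndimage.sum_labels(np.ones_like(raw_labels), raw_labels, index=ids).astype(int)
    means = ndimage.mean(filtered, labels=raw_labels, index=ids)
    # relabel 1..K in order of descending area (stable for ties)
    order = np.argsort(-areas, kind="stable")
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    remap[ids[order]] = np.arange(1, n_raw + 1)
    labels = remap[raw_labels]

    segmented_area = int(areas.sum())
    half_max = 0.5 * filtered.max()
    bright_area = int(np.count_nonzero((labels > 0) & (filtered >= half_max)))
    return SegmentationResult(
        labels=labels,
        region_means=[(k + 1, float(means[order[k]])) for k in range(n_raw)],
        region_areas=[(k + 1, int(areas[order[k]])) for k in range(n_raw)],
        segmented_area_px=segmented_area,
        bright_area_px=bright_area,
        bright_ratio=bright_area / segmented_area,
        threshold=thr,
        filtered=filtered,
    )


def bright_area_ratio(img: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of masked pixels at or above half the image maximum.

    The maximum is taken over the whole (filtered) image, following the
    half-max convention used to delineate hyperpolarised areas.
    """
    img = as_intensity_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("no segmented signal: mask is empty")
    half_max = 0.5 * img.max()
    return float(np.count_nonzero(mask & (img >= half_max)) / n_mask)


@dataclass(frozen=True)
class FccpResponse:
    """Uncoupler-response statistic for a before/after image or signal pair."""

    f_before: float
    f_after: float

    @property
    def response_pct(self) -> float:
        return 100.0 * (self.f_before - self.f_after) / self.f_before


def fccp_response(f_before: float, f_after: float) -> FccpResponse:
    """Percentage loss of fluorescence after FCCP.

    ``response_pct = 100 * (f_before - f_after) / f_before``; negative when
    the signal rises after the uncoupler.
    """
    if not np.isfinite(f_before) or f_before <= 0:
        raise ValueError(f"no pre-uncoupler signal: f_before must be > 0, got {f_before}")
    if not np.isfinite(f_after) or f_after < 0:
        raise ValueError(f"f_after must be a finite non-negative value, got {f_after}")
    return FccpResponse(f_before=float(f_before), f_after=float(f_after))


def fccp_response_from_images(
    before: np.ndarray,
    after: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> tuple[FccpResponse, SegmentationResult]:
    """FCCP response from an image pair.

    The before image is segmented; the mean filtered fluorescence over the
    segmented pixels, in both images, gives ``f_before`` and ``f_after``.
    Using the pre-uncoupler mask for both images keeps the comparison on
    the same structures even after the signal collapses.
    """
    cfg = cfg or SegmentationConfig()
    seg = segment_mitochondria(before, cfg)
    if seg.n_regions == 0:
        raise ValueError("no segmented signal in the pre-FCCP image")
    after_filtered = adaptive_wiener(as_intensity_image(after), cfg.wiener_window, cfg.border_mode)
    if after_filtered.shape != seg.labels.shape:
        raise ValueError("before/after images must have the same shape")
    m = seg.mask
    return fccp_response(float(seg.filtered[m].mean()), float(after_filtered[m].mean())), seg
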