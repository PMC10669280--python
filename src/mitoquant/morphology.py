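"""Binary mathematical morphology on segmentation masks.

Thin, explicitly-specified wrappers over :mod:`scipy.ndimage` and
:mod:`skimage.morphology`, so the segmentation pipeline depends on one
surface with fixed conventions:

* dilation is the union of structuring-element translates over the
  foreground; erosion keeps pixels whose element translate lies fully in
  the foreground (pixels outside the image count as background);
* hole filling uses 4-connectivity for the background, so diagonal
  "leaks" do not empty a hole;
* small-object removal uses 8-connectivity for the foreground.

All elements used here are symmetric about their origin.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import diamond, disk, remove_small_objects

__all__ = [
    "structuring_element",
    "morph_dilate",
    "morph_erode",
    "morph_fill_holes",
    "morph_remove_small",
]

# 4-connected structure used for background components in hole filling.
_BG_STRUCTURE = ndimage.generate_binary_structure(2, 1)
# 8-connected structure for foreground labelling.
FG_STRUCTURE_8 = ndimage.generate_binary_structure(2, 2)


def structuring_element(name: str, radius: int = 1) -> list[np.ndarray]:
    """Return the named structuring element as a list of binary arrays.

    A list is returned because some recipes (``"lines"``) are applied as a
    sequence of elements; single elements come back as a one-item list.

    Parameters
    ----------
    name:
        One of ``"diamond"``, ``"square"``, ``"disk"``,
        ``"line_horizontal"``, ``"line_vertical"``, or ``"lines"`` (the
        horizontal then vertical line of length ``2 * radius + 1``, applied
        in sequence — the classic recipe for closing gradient outlines).
    radius:
        Element radius; the element spans ``2 * radius + 1`` pixels.
    """
    if radius < 1:
        raise ValueError(f"structuring element radius must be >= 1, got {radius}")
    length = 2 * radius + 1
    if name == "diamond":
        return [diamond(radius).astype(bool)]
    if name == "square":
        return [np.ones((length, length), dtype=bool)]
    if name == "disk":
        return [disk(radius).astype(bool)]
    if name == "line_horizontal":
        return [np.ones((1, length), dtype=bool)]
    if name == "line_vertical":
        return [np.ones((length, 1), dtype=bool)]
    if name == "lines":
        return [np.ones((1, length), dtype=bool), np.ones((length, 1), dtype=bool)]
    raise ValueError(f"unknown structuring element {name!r}")


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


def _check_elements(element: np.ndarray | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(element, np.ndarray):
        elements = [element]
    else:
        elements = list(element)
    checked = []
    for el in elements:
        el = np.asarray(el).astype(bool)
        if el.size == 0 or not el.any():
            raise ValueError("structuring element must be non-empty")
        centre = tuple(s // 2 for s in el.shape)
        if not el[centre]:
            raise ValueError("structuring element must contain its origin")
        checked.append(el)
    return checked


def morph_dilate(mask: np.ndarray, element: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Dilate ``mask`` by one element, or by a sequence of elements in order."""
    out = _check_mask(mask)
    for el in _check_elements(element):
        out = ndimage.binary_dilation(out, structure=el)
    return out


def morph_erode(mask: np.ndarray, element: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Erode ``mask``; out-of-image pixels count as background."""
    out = _check_mask(mask)
    for el in _check_elements(element):
        out = ndimage.binary_erosion(out, structure=el, border_value=0)
    return out


def morph_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected (4-conn) to the image border."""
    return ndimage.binary_fill_holes(_check_mask(mask), structure=_BG_STRUCTURE)


def morph_remove_small(mask: np.ndarray, min_object_px: int = 2) -> np.ndarray:
    """Drop 8-connected components with area below ``min_object_px`` pixels."""
    if min_object_px < 1:
        raise ValueError(f"min_object_px must be >= 1, got {min_object_px}")
    mask = _check_mask(mask)
    # max_size removes components with area <= max_size, i.e. < min_object_px
    return remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)
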