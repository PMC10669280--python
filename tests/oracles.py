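"""Brute-force reference implementations used only by the tests.

Each oracle is a direct transcription of the mathematical definition
(sliding windows, set arithmetic, flood fill), written without any of the
vectorised library calls the package itself uses, so agreement is a real
two-route check.  Padding follows the package's border convention:
edge-including reflection (``np.pad(mode="symmetric")``, which is what
scipy.ndimage calls ``reflect``).
"""

from __future__ import annotations

import numpy as np


def wiener_oracle(img: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Sliding-window adaptive Wiener filter, one pixel at a time."""
    img = np.asarray(img, dtype=float)
    wr, wc = window
    pr, pc = wr // 2, wc // 2
    pad = np.pad(img, ((pr, pr), (pc, pc)), mode="symmetric")
    h, w = img.shape
    means = np.empty((h, w))
    variances = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = pad[i : i + wr, j : j + wc]
            means[i, j] = win.mean()
            variances[i, j] = win.var()
    noise = variances.mean()
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            v = variances[i, j]
            den = max(v, noise)
            gain = max(v - noise, 0.0) / den if den > 0 else 0.0
            out[i, j] = means[i, j] + gain * (img[i, j] - means[i, j])
    return np.clip(out, 0.0, None)


SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T


def sobel_oracle(img: np.ndarray) -> np.ndarray:
    """3x3 Sobel magnitude by explicit per-pixel correlation."""
    img = np.asarray(img, dtype=float)
    pad = np.pad(img, 1, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = pad[i : i + 3, j : j + 3]
            gx = float((win * SOBEL_X).sum())
            gy = float((win * SOBEL_Y).sum())
            out[i, j] = np.sqrt(gx * gx + gy * gy)
    return out


def _element_offsets(element: np.ndarray) -> list[tuple[int, int]]:
    eh, ew = element.shape
    oy, ox = eh // 2, ew // 2
    return [
        (i - oy, j - ox)
        for i in range(eh)
        for j in range(ew)
        if element[i, j]
    ]


def dilate_oracle(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Union of element translates centred on every foreground pixel."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    offsets = _element_offsets(np.asarray(element, dtype=bool))
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in offsets:
                y, x = i + di, j + dj
                if 0 <= y < h and 0 <= x < w:
                    out[y, x] = True
    return out


def erode_oracle(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Pixels whose full element translate lies inside the foreground."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    offsets = _element_offsets(np.asarray(element, dtype=bool))
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            keep = True
            for di, dj in offsets:
                y, x = i + di, j + dj
                if not (0 <= y < h and 0 <= x < w) or not mask[y, x]:
                    keep = False
                    break
            out[i, j] = keep
    return out


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Foreground plus background components not 4-connected to the border."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    reached = np.zeros_like(mask)
    stack = [
        (i, j)
        for i in range(h)
        for j in range(w)
        if (i in (0, h - 1) or j in (0, w - 1)) and not mask[i, j]
    ]
    for i, j in stack:
        reached[i, j] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            y, x = i + di, j + dj
            if 0 <= y < h and 0 <= x < w and not mask[y, x] and not reached[y, x]:
                reached[y, x] = True
                stack.append((y, x))
    return mask | ~reached


def remove_small_oracle(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected foreground components with area < min_px."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    neighbours = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for i in range(h):
        for j in range(w):
            if not mask[i, j] or seen[i, j]:
                continue
            comp = [(i, j)]
            seen[i, j] = True
            idx = 0
            while idx < len(comp):
                y, x = comp[idx]
                idx += 1
                for di, dj in neighbours:
                    yy, xx = y + di, x + dj
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        comp.append((yy, xx))
            if len(comp) >= min_px:
                for y, x in comp:
                    out[y, x] = True
    return out


def ellipse_raster_oracle(
    shape: tuple[int, int], centre: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    """Pixel-by-pixel rotated-ellipse membership test."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for i in range(h):
        for j in range(w):
            dy, dx = i - centre[0], j - centre[1]
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            out[i, j] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out
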