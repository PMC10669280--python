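"""Reading and writing the pipeline's file formats.

TIFF images go through :mod:`tifffile`; tables through :mod:`pandas`;
configuration through YAML key-value files mirroring
:class:`~mitoquant.imaging.SegmentationConfig`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import SegmentationConfig, SegmentationResult, as_intensity_image

__all__ = [
    "read_image",
    "read_image_pair",
    "write_image",
    "load_segmentation_config",
    "save_segmentation_config",
    "write_segmentation_outputs",
    "save_overlay_png",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel grayscale TIFF as a float64 intensity image."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    return as_intensity_image(arr)


def read_image_pair(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-page TIFF as an ordered (before, after) image pair."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"{path}: expected exactly 2 pages, got shape {arr.shape}")
    return as_intensity_image(arr[0]), as_intensity_image(arr[1])


def write_image(path: str | Path, img: np.ndarray, bit_depth: int = 16) -> None:
    """Write an intensity image as an 8- or 16-bit grayscale TIFF."""
    img = as_intensity_image(img)
    if bit_depth == 16:
        out = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    elif bit_depth == 8:
        out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    tifffile.imwrite(str(path), out)


def load_segmentation_config(path: str | Path) -> SegmentationConfig:
    """Load a YAML key-value file into a :class:`SegmentationConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "wiener_window" in raw:
        raw["wiener_window"] = tuple(raw["wiener_window"])
    return SegmentationConfig(**raw)


def save_segmentation_config(path: str | Path, cfg: SegmentationConfig) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.__dict__.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_segmentation_outputs(
    out_dir: str | Path, result: SegmentationResult, stem: str = "segmentation"
) -> tuple[Path, Path]:
    """Write per-region CSV and JSON summary; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    regions = pd.DataFrame(
        {
            "region_id": [rid for rid, _ in result.region_areas],
            "area_px": [a for _, a in result.region_areas],
            "mean_intensity": [m for _, m in result.region_means],
        }
    )
    csv_path = out_dir / f"{stem}_regions.csv"
    regions.to_csv(csv_path, index=False)
    summary = {
        "n_regions": result.n_regions,
        "segmented_area_px": result.segmented_area_px,
        "bright_area_px": result.bright_area_px,
        "bright_ratio": result.bright_ratio,
        "gradient_threshold": result.threshold,
    }
    json_path = out_dir / f"{stem}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path


def save_overlay_png(path: str | Path, img: np.ndarray, result: SegmentationResult) -> None:
    """Save a PNG of the image with labelled-region boundaries overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, cmap="gray")
    boundaries = find_boundaries(result.labels, mode="outer")
    overlay = np.zeros((*img.shape, 4))
    overlay[boundaries] = (1.0, 0.2, 0.2, 1.0)
    ax.imshow(overlay)
    ax.set_axis_off()
    fig.savefig(str(path), bbox_inches="tight", dpi=150)
    plt.close(fig)
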