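"""Synthetic instrument emulators with known ground truth.

Every input the analysis modules consume can be generated here with the
true answer attached, so recovery can be measured directly:

* :func:`gen_mito_image` — a fluorescence-microscope stand-in: rod/blob
  (elliptical) mitochondrial profiles on a dark background, a controllable
  fraction of "hyperpolarised" bright pixels, an after-uncoupler frame
  with the signal collapsed toward background, and Poisson-Gaussian
  (shot + read) noise.
* :func:`gen_resp_trace` — a flux-analyser stand-in: four-stage OCR/ECAR
  plateaus (basal, oligomycin, FCCP, rotenone/antimycin) with Gaussian
  noise and the exact stress-test parameters implied by the noiseless
  levels.
* :func:`gen_plate` — a plate-reader stand-in: Gaussian readings around
  true group means, with blank / positive-control / untreated-control
  roles assigned.

All generators are fully deterministic given their seed, and each truth
object carries its parameters in the same types the analysis modules
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .respirometry import (
    ATPRates,
    BioenergeticConstants,
    MitoStressParams,
    RespTrace,
    StageLevels,
    compute_atp_rates,
    compute_mito_stress,
)

__all__ = [
    "ImageTruth",
    "TraceTruth",
    "PlateTruth",
    "gen_mito_image",
    "gen_resp_trace",
    "gen_plate",
]


@dataclass
class ImageTruth:
    """Ground truth for one synthetic before/after image pair."""

    seed: int
    object_labels: np.ndarray = field(repr=False)
    bright_mask: np.ndarray = field(repr=False)
    bright_fraction: float
    realized_bright_fraction: float
    depolarisation: float
    base_intensity: float
    bright_multiplier: float
    background: float
    gauss_sigma: float
    poisson: bool
    clean_before: np.ndarray = field(repr=False)
    clean_after: np.ndarray = field(repr=False)

    @property
    def object_mask(self) -> np.ndarray:
        return self.object_labels > 0


def _rasterize_ellipse(
    shape: tuple[int, int], centre: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    """Pixels whose centres satisfy the rotated-ellipse inequality."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - centre[0]
    dx = cc - centre[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def gen_mito_image(
    n_objects: int = 10,
    size: tuple[int, int] = (256, 256),
    major_axis_range: tuple[float, float] = (10.0, 24.0),
    minor_axis_range: tuple[float, float] = (4.0, 8.0),
    base_intensity: float = 100.0,
    bright_fraction: float = 0.3,
    bright_multiplier: float = 3.0,
    background: float = 5.0,
    depolarisation: float = 0.6,
    gauss_sigma: float = 4.0,
    poisson: bool = True,
    min_gap_px: int = 6,
    max_tries: int = 200,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Simulate a TMRM image pair (before / after uncoupler) with truth.

    Objects are non-overlapping rotated ellipses (semi-axes drawn from the
    given ranges) at ``base_intensity`` over a dim ``background``.  A
    fraction ``bright_fraction`` of object pixels, drawn uniformly across
    objects, is set to ``bright_multiplier * base_intensity`` — the
    hyperpolarised pool.  The after frame scales object signal toward
    background by ``(1 - depolarisation)``, emulating the FCCP-driven
    collapse of the membrane potential.  Poisson shot noise (if enabled)
    plus Gaussian read noise is applied independently to each frame.

    ``min_gap_px`` keeps placed objects at least that far apart so the
    segmentation pipeline's gap-closing dilation cannot merge them.
    Raises if ``n_objects`` cannot be packed after ``max_tries`` draws per
    object.
    """
    if not 0.0 <= bright_fraction <= 1.0:
        raise ValueError(f"bright_fraction must be in [0, 1], got {bright_fraction}")
    if not 0.0 <= depolarisation <= 1.0:
        raise ValueError(f"depolarisation must be in [0, 1], got {depolarisation}")
    rng = np.random.default_rng(seed)
    h, w = size
    labels = np.zeros(size, dtype=np.int32)
    # forbidden zone: existing objects padded by min_gap_px (Chebyshev)
    from scipy import ndimage as ndi

    pad_structure = np.ones((2 * min_gap_px + 1, 2 * min_gap_px + 1), dtype=bool)
    forbidden = np.zeros(size, dtype=bool)
    for k in range(1, n_objects + 1):
        placed = False
        for _ in range(max_tries):
            a = rng.uniform(*major_axis_range)
            b = rng.uniform(*minor_axis_range)
            theta = rng.uniform(0.0, np.pi)
            margin = a + 2.0
            if 2 * margin >= min(h, w):
                raise ValueError("objects too large for the field")
            centre = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            mask = _rasterize_ellipse(size, centre, a, b, theta)
            if not mask.any() or (mask & forbidden).any():
                continue
            labels[mask] = k
            forbidden |= ndi.binary_dilation(mask, structure=pad_structure)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place object {k}/{n_objects} after {max_tries} tries; "
                "reduce n_objects or object size"
            )

    object_mask = labels > 0
    obj_idx = np.flatnonzero(object_mask.ravel())
    n_bright = int(round(bright_fraction * len(obj_idx)))
    bright_flat = rng.choice(obj_idx, size=n_bright, replace=False) if n_bright else np.empty(0, int)
    bright_mask = np.zeros(size, dtype=bool)
    bright_mask.ravel()[bright_flat] = True
    realized_f = n_bright / len(obj_idx) if len(obj_idx) else 0.0

    clean_before = np.full(size, float(background))
    clean_before[object_mask] = base_intensity
    clean_before[bright_mask] = bright_multiplier * base_intensity
    clean_after = background + (1.0 - depolarisation) * (clean_before - background)

    def _noisy(clean: np.ndarray) -> np.ndarray:
        img = rng.poisson(clean).astype(float) if poisson else clean.copy()
        img += rng.normal(0.0, gauss_sigma, size=clean.shape)
        return np.clip(img, 0.0, None)

    truth = ImageTruth(
        seed=-1 if seed is None else int(seed),
        object_labels=labels,
        bright_mask=bright_mask,
        bright_fraction=bright_fraction,
        realized_bright_fraction=realized_f,
        depolarisation=depolarisation,
        base_intensity=base_intensity,
        bright_multiplier=bright_multiplier,
        background=background,
        gauss_sigma=gauss_sigma,
        poisson=poisson,
        clean_before=clean_before,
        clean_after=clean_after,
    )
    return _noisy(clean_before), _noisy(clean_after), truth


@dataclass
class TraceTruth:
    """Noiseless stage levels and the exact parameters they imply."""

    seed: int
    levels: StageLevels
    params: MitoStressParams
    rates: ATPRates
    noise_sigma: float


def gen_resp_trace(
    levels: StageLevels | None = None,
    n_points: int = 3,
    noise_sigma: float = 2.0,
    noise_sigma_ecar: float = 0.5,
    n_wells: int = 1,
    group: str = "control",
    well_prefix: str = "A",
    interval_min: float = 6.5,
    consts: BioenergeticConstants | None = None,
    seed: int | None = None,
) -> tuple[list[RespTrace], TraceTruth]:
    """Simulate staged OCR/ECAR wells around true plateau levels.

    Default levels (basal 100, oligomycin 40, FCCP 180, rot/AA 20 pmol
    O2/min; basal ECAR 20 mpH/min) describe a healthy well with coupling
    efficiency 0.75 and a glycolytic ATP fraction near 0.2.  Each stage
    contributes ``n_points`` measurements at its plateau plus Gaussian
    noise.  ECAR rises modestly after oligomycin (compensatory
    glycolysis); only the basal ECAR enters the ATP-rate calculation.
    """
    levels = levels or StageLevels(100.0, 40.0, 180.0, 20.0, 20.0)
    if not (
        levels.fccp_max >= levels.basal_last >= levels.oligo_min >= levels.rot_aa_min >= 0.0
    ):
        raise ValueError(
            "stage levels must satisfy fccp_max >= basal_last >= oligo_min >= rot_aa_min >= 0"
        )
    rng = np.random.default_rng(seed)
    ocr_plateau = {
        "basal": levels.basal_last,
        "oligomycin": levels.oligo_min,
        "fccp": levels.fccp_max,
        "rot_aa": levels.rot_aa_min,
    }
    ecar_plateau = {
        "basal": levels.basal_ecar,
        "oligomycin": 1.5 * levels.basal_ecar,
        "fccp": 1.5 * levels.basal_ecar,
        "rot_aa": 1.2 * levels.basal_ecar,
    }
    stages = [s for s in ocr_plateau for _ in range(n_points)]
    times = interval_min * np.arange(len(stages))
    traces = []
    for i in range(n_wells):
        ocr = np.array([ocr_plateau[s] for s in stages]) + rng.normal(0, noise_sigma, len(stages))
        ecar = np.array([ecar_plateau[s] for s in stages]) + rng.normal(
            0, noise_sigma_ecar, len(stages)
        )
        traces.append(
            RespTrace(
                well_id=f"{well_prefix}{i + 1}",
                group=group,
                time_min=times,
                stage=list(stages),
                ocr=ocr,
                ecar=ecar,
            )
        )
    params = compute_mito_stress(levels)
    rates = compute_atp_rates(levels, params, consts)
    truth = TraceTruth(
        seed=-1 if seed is None else int(seed),
        levels=levels,
        params=params,
        rates=rates,
        noise_sigma=noise_sigma,
    )
    return traces, truth


@dataclass
class PlateTruth:
    """True group means and noise level behind a simulated plate."""

    seed: int
    group_means: dict[str, float]
    control: str
    noise_sigma: float
    blank_mean: float | None
    positive_mean: float | None


def gen_plate(
    group_means: dict[str, float],
    control: str,
    noise_sigma: float = 5.0,
    replicates: int = 5,
    parallels: int = 1,
    blank_mean: float | None = None,
    positive_mean: float | None = None,
    control_wells: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, PlateTruth]:
    """Simulate a long-format plate table with Gaussian well noise.

    ``group_means`` maps group labels (including the control) to true
    readings.  ``parallels`` wells are read per biological replicate
    (parallel loadings of the same sample get the same true value and
    independent noise).  Blank and positive-control wells are added when
    their true means are given, each measured ``control_wells`` times.
    """
    if control not in group_means:
        raise ValueError(f"control group {control!r} must appear in group_means")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for label, mean in group_means.items():
        role = "untreated_control" if label == control else "sample"
        for rep in range(1, replicates + 1):
            for _ in range(parallels):
                well += 1
                rows.append(
                    {
                        "well": f"W{well:03d}",
                        "group": label,
                        "replicate": rep,
                        "role": role,
                        "reading": mean + rng.normal(0.0, noise_sigma),
                    }
                )
    for role, mean in (("blank", blank_mean), ("positive_control", positive_mean)):
        if mean is None:
            continue
        for rep in range(1, control_wells + 1):
            well += 1
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "group": role,
                    "replicate": rep,
                    "role": role,
                    "reading": mean + rng.normal(0.0, noise_sigma),
                }
            )
    truth = PlateTruth(
        seed=-1 if seed is None else int(seed),
        group_means=dict(group_means),
        control=control,
        noise_sigma=noise_sigma,
        blank_mean=blank_mean,
        positive_mean=positive_mean,
    )
    return pd.DataFrame(rows), truth
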