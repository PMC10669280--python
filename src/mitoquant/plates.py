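"""Plate-reader assay quantification: haemolysis and TMRM plate potential.

Plates arrive as long-format tables with columns
``well, group, replicate, role, reading`` where ``role`` is one of
``sample``, ``blank``, ``positive_control``, ``untreated_control``.

Haemolysis scales supernatant absorbance (415 nm, released haemoglobin)
between a blank (0%) and a detergent-lysed positive control (100%, 1%
Triton X-100).  The TMRM plate readout reports background-subtracted
fluorescence relative to the untreated-control mean, as a percentage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "validate_plate",
    "read_plate_csv",
    "haemolysis_pct",
    "haemolysis_table",
    "tmrm_plate_potential",
]

ROLES = ("sample", "blank", "positive_control", "untreated_control")


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    required = {"well", "group", "replicate", "role", "reading"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    unknown = set(plate["role"]) - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles {sorted(unknown)}; expected one of {ROLES}")
    if not np.all(np.isfinite(plate["reading"].to_numpy(dtype=float))):
        raise ValueError("plate readings must be finite")
    return plate


def read_plate_csv(path) -> pd.DataFrame:
    return validate_plate(pd.read_csv(path))


def haemolysis_pct(a_sample: float, a_blank: float, a_triton: float) -> float:
    """Haemolysis percentage of one absorbance reading.

    ``100 * (a_sample - a_blank) / (a_triton - a_blank)``; the blank
    anchors 0% and the Triton-lysed positive control anchors 100%.
    Adding a constant to all three absorbances leaves the result
    unchanged (affine invariance), so blank-subtraction conventions
    upstream do not matter.
    """
    if not a_triton > a_blank:
        raise ValueError(
            f"positive control failed: a_triton ({a_triton}) must exceed a_blank ({a_blank})"
        )
    return 100.0 * (float(a_sample) - float(a_blank)) / (float(a_triton) - float(a_blank))


def _averaged_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Average parallel wells of the same (group, replicate, role) pair."""
    return (
        plate.groupby(["group", "replicate", "role"], as_index=False, sort=False)["reading"]
        .mean()
    )


def haemolysis_table(plate: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample haemolysis percentages and per-group mean ± SD summaries.

    Duplicate wells ("parallels") of the same biological replicate are
    averaged before the percentage formula.  Returns
    ``(per_sample, per_group)`` DataFrames; blanks come out at exactly 0%
    and positive controls at exactly 100% by construction.
    """
    plate = validate_plate(plate)
    if not (plate["role"] == "blank").any():
        raise ValueError("haemolysis plate needs at least one blank well")
    if not (plate["role"] == "positive_control").any():
        raise ValueError("haemolysis plate needs at least one positive_control well")
    avg = _averaged_replicates(plate)
    a_blank = avg.loc[avg["role"] == "blank", "reading"].mean()
    a_triton = avg.loc[avg["role"] == "positive_control", "reading"].mean()
    if not a_triton > a_blank:
        raise ValueError("positive control failed: Triton absorbance not above blank")
    per_sample = avg.copy()
    per_sample["haemolysis_pct"] = [
        haemolysis_pct(r, a_blank, a_triton) for r in per_sample["reading"]
    ]
    per_group = (
        per_sample.groupby(["group", "role"], as_index=False)["haemolysis_pct"]
        .agg(mean="mean", sd="std", n="count")
    )
    return per_sample, per_group


def tmrm_plate_potential(plate: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative mitochondrial membrane potential from a TMRM plate.

    Per well: blank-mean-subtracted fluorescence (if blank wells are
    present) divided by the untreated-control mean, times 100.  Returns
    ``(per_sample, per_group)``; the control group averages 100% by
    construction.
    """
    plate = validate_plate(plate)
    if not (plate["role"] == "untreated_control").any():
        raise ValueError("TMRM plate needs at least one untreated_control well")
    avg = _averaged_replicates(plate)
    background = 0.0
    has_blanks = (avg["role"] == "blank").any()
    if has_blanks:
        background = avg.loc[avg["role"] == "blank", "reading"].mean()
    corrected = avg["reading"] - background
    control_mean = corrected[avg["role"] == "untreated_control"].mean()
    if not control_mean > 0:
        raise ValueError("untreated-control mean fluorescence is not positive")
    per_sample = avg.copy()
    per_sample["potential_pct"] = 100.0 * corrected / control_mean
    keep = per_sample["role"].isin(["sample", "untreated_control"])
    per_group = (
        per_sample[keep]
        .groupby(["group", "role"], as_index=False)["potential_pct"]
        .agg(mean="mean", sd="std", n="count")
    )
    return per_sample, per_group
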