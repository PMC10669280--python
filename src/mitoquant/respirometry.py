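"""Mito-stress-test parameters and ATP production rates from flux traces.

A mito stress test records oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) per well through four
injection stages: basal, oligomycin (ATP-synthase inhibitor), FCCP
(uncoupler), and rotenone + antimycin A (electron-transport shutdown).
From the stage levels the classical partition follows::

    non_mito     = min OCR after rotenone/antimycin
    basal        = last basal OCR        - non_mito
    proton_leak  = min oligomycin OCR    - non_mito
    atp_linked   = basal - proton_leak
    maximal      = max FCCP OCR          - non_mito
    spare        = maximal - basal
    coupling     = atp_linked / basal

ATP production rates convert ATP-linked OCR to a mitochondrial rate via
the P/O ratio (ATP per O atom, 2 O atoms per O2) and attribute the
remainder of the proton efflux rate — basal ECAR converted through the
medium buffer factor, minus the respiration-derived acidification
(CCF x basal OCR) — to glycolysis at one ATP per exported lactate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "RespTrace",
    "StageLevels",
    "MitoStressParams",
    "ATPRates",
    "BioenergeticConstants",
    "extract_stage_levels",
    "compute_mito_stress",
    "compute_atp_rates",
    "analyze_trace",
    "analyze_traces",
    "group_summary",
    "read_resp_csv",
    "trace_recovery_check",
]

STAGES = ("basal", "oligomycin", "fccp", "rot_aa")

PARAM_FIELDS = (
    "non_mito",
    "basal",
    "proton_leak",
    "atp_linked",
    "maximal",
    "spare",
    "coupling_efficiency",
)


@dataclass
class RespTrace:
    """One well's staged OCR/ECAR time series."""

    well_id: str
    group: str
    time_min: np.ndarray
    stage: list[str]
    ocr: np.ndarray
    ecar: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        n = len(self.time_min)
        if not (len(self.stage) == len(self.ocr) == len(self.ecar) == n):
            raise ValueError("time_min, stage, ocr, ecar must have equal length")
        if n == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.ocr)) and np.all(np.isfinite(self.ecar))):
            raise ValueError("OCR and ECAR must be finite")
        unknown = set(self.stage) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage labels {sorted(unknown)}; expected {STAGES}")
        # stages must appear contiguously in assay order, each at least once
        order = [STAGES.index(s) for s in self.stage]
        if np.any(np.diff(order) < 0):
            raise ValueError("stages out of order: expected basal -> oligomycin -> fccp -> rot_aa")
        missing = [s for s in STAGES if s not in self.stage]
        if missing:
            raise ValueError(f"missing stage(s): {missing}")

    def stage_values(self, stage: str, which: str = "ocr") -> np.ndarray:
        sel = np.array([s == stage for s in self.stage])
        return (self.ocr if which == "ocr" else self.ecar)[sel]


@dataclass(frozen=True)
class StageLevels:
    """Representative OCR level per stage, plus basal ECAR."""

    basal_last: float
    oligo_min: float
    fccp_max: float
    rot_aa_min: float
    basal_ecar: float

    def __post_init__(self) -> None:
        vals = (self.basal_last, self.oligo_min, self.fccp_max, self.rot_aa_min, self.basal_ecar)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("stage levels must be finite")
        if any(v < 0 for v in vals):
            warnings.warn("negative stage level encountered", stacklevel=2)


@dataclass(frozen=True)
class MitoStressParams:
    """Partitioned respiration (all OCR components in pmol O2/min)."""

    non_mito: float
    basal: float
    proton_leak: float
    atp_linked: float
    maximal: float
    spare: float
    coupling_efficiency: float
    warnings: tuple[str, ...] = field(default=(), compare=False)


@dataclass(frozen=True)
class ATPRates:
    """ATP production rates (pmol ATP/min) and the glycolytic fraction."""

    mito_atp: float
    glyco_atp: float
    total_atp: float
    glyco_fraction: float
    warnings: tuple[str, ...] = field(default=(), compare=False)


@dataclass(frozen=True)
class BioenergeticConstants:
    """Conversion constants for ATP-rate calculations.

    None of these are measured by the assay itself; they are methodology
    conventions, override them to match your instrument and medium.

    p_o_ratio:
        ATP synthesised per oxygen atom reduced (default 2.75).
    o_atoms_per_o2:
        2 by stoichiometry.
    buffer_factor:
        Medium buffering, mpH per (pmol H+/min); divides ECAR into a
        proton efflux rate.
    ccf:
        CO2-derived acidification contribution factor, pmol H+ per
        pmol O2 of mitochondrial respiration (default 0.61).
    atp_per_lactate:
        ATP per lactate exported by glycolysis (1 by stoichiometry).
    """

    p_o_ratio: float = 2.75
    o_atoms_per_o2: float = 2.0
    buffer_factor: float = 0.15
    ccf: float = 0.61
    atp_per_lactate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_o_ratio", "o_atoms_per_o2", "buffer_factor", "ccf", "atp_per_lactate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def extract_stage_levels(trace: RespTrace) -> StageLevels:
    """Pick the conventional representative value per stage.

    Last basal point (cells settled), minimum under oligomycin (full
    ATP-synthase inhibition), maximum under FCCP (peak uncoupled rate),
    minimum under rotenone/antimycin (non-mitochondrial floor).
    """
    return StageLevels(
        basal_last=float(trace.stage_values("basal")[-1]),
        oligo_min=float(trace.stage_values("oligomycin").min()),
        fccp_max=float(trace.stage_values("fccp").max()),
        rot_aa_min=float(trace.stage_values("rot_aa").min()),
        basal_ecar=float(trace.stage_values("basal", "ecar")[-1]),
    )


def compute_mito_stress(levels: StageLevels) -> MitoStressParams:
    """Partition OCR stage levels into the stress-test parameters."""
    non_mito = levels.rot_aa_min
    basal = levels.basal_last - non_mito
    if basal <= 0:
        raise ValueError(
            "no mitochondrial respiration above non-mitochondrial floor "
            f"(basal_last={levels.basal_last}, rot_aa_min={levels.rot_aa_min})"
        )
    proton_leak = levels.oligo_min - non_mito
    atp_linked = basal - proton_leak
    maximal = levels.fccp_max - non_mito
    notes: list[str] = []
    if atp_linked < 0:
        notes.append("negative atp_linked: oligomycin OCR above basal OCR")
    if proton_leak < 0:
        notes.append("negative proton_leak: oligomycin OCR below rot/AA floor")
    return MitoStressParams(
        non_mito=non_mito,
        basal=basal,
        proton_leak=proton_leak,
        atp_linked=atp_linked,
        maximal=maximal,
        spare=maximal - basal,
        coupling_efficiency=atp_linked / basal,
        warnings=tuple(notes),
    )


def compute_atp_rates(
    levels: StageLevels,
    params: MitoStressParams,
    consts: BioenergeticConstants | None = None,
) -> ATPRates:
    """Mitochondrial and glycolytic ATP production rates.

    ``mito_atp = atp_linked * o_atoms_per_o2 * p_o_ratio``.  The total
    proton efflux rate is ``basal_ecar / buffer_factor``; subtracting the
    respiration-derived share ``ccf * basal`` leaves the
    glycolysis-attributable efflux, converted one-to-one to ATP.
    Negative computed efflux is clamped to zero with a warning note.
    """
    consts = consts or BioenergeticConstants()
    mito_atp = params.atp_linked * consts.o_atoms_per_o2 * consts.p_o_ratio
    efflux = levels.basal_ecar / consts.buffer_factor - consts.ccf * params.basal
    notes: list[str] = []
    if efflux < 0:
        notes.append("negative glycolytic proton efflux clamped to 0")
        efflux = 0.0
    glyco_atp = consts.atp_per_lactate * efflux
    total = mito_atp + glyco_atp
    return ATPRates(
        mito_atp=mito_atp,
        glyco_atp=glyco_atp,
        total_atp=total,
        glyco_fraction=glyco_atp / total if total > 0 else 0.0,
        warnings=tuple(notes),
    )


def analyze_trace(
    trace: RespTrace, consts: BioenergeticConstants | None = None
) -> tuple[StageLevels, MitoStressParams, ATPRates]:
    levels = extract_stage_levels(trace)
    params = compute_mito_stress(levels)
    rates = compute_atp_rates(levels, params, consts)
    return levels, params, rates


def analyze_traces(
    traces: list[RespTrace], consts: BioenergeticConstants | None = None
) -> pd.DataFrame:
    """Per-well stress-test parameters and ATP rates as a tidy DataFrame."""
    rows = []
    for tr in traces:
        _, params, rates = analyze_trace(tr, consts)
        row: dict[str, object] = {"well": tr.well_id, "group": tr.group}
        for f in PARAM_FIELDS:
            row[f] = getattr(params, f)
        for f in ("mito_atp", "glyco_atp", "total_atp", "glyco_fraction"):
            row[f] = getattr(rates, f)
        row["flags"] = "; ".join(params.warnings + rates.warnings)
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(per_well: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (ddof=1), and n per group for every numeric parameter."""
    numeric = per_well.select_dtypes("number").columns
    out = per_well.groupby("group")[list(numeric)].agg(["mean", "std", "count"])
    out.columns = [f"{p}_{s}".replace("_count", "_n") for p, s in out.columns]
    return out.reset_index()


def read_resp_csv(path) -> list[RespTrace]:
    """Read a long-format trace CSV: ``well,group,time_min,stage,ocr,ecar``."""
    df = pd.read_csv(path)
    required = {"well", "group", "time_min", "stage", "ocr", "ecar"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for (well, group), sub in df.groupby(["well", "group"], sort=False):
        sub = sub.sort_values("time_min")
        traces.append(
            RespTrace(
                well_id=str(well),
                group=str(group),
                time_min=sub["time_min"].to_numpy(),
                stage=list(sub["stage"]),
                ocr=sub["ocr"].to_numpy(),
                ecar=sub["ecar"].to_numpy(),
            )
        )
    return traces


def trace_recovery_check(truth: MitoStressParams, estimated: MitoStressParams) -> pd.DataFrame:
    """Absolute and relative error of every parameter against ground truth."""
    rows = []
    for f in PARAM_FIELDS:
        t, e = getattr(truth, f), getattr(estimated, f)
        rows.append(
            {
                "parameter": f,
                "truth": t,
                "estimate": e,
                "abs_error": abs(e - t),
                "rel_error": abs(e - t) / abs(t) if t != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
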