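"""Global and regional end-diastolic volume difference statistics.

The global comparison is the signed difference ΔEDV = EDV_echo − EDV_CMR in
millilitres. The regional comparison expresses, for every region r of the
14-segment parcellation, the echo-minus-CMR volume difference as a fraction
of the *total* CMR-derived volume:

    ΔEDV_r = (EDV_r,echo − EDV_r,CMR) / EDV_CMR

reported in percent. Normalizing by the CMR total (not the regional volume)
makes the fractions additive — they sum to the global relative difference —
and comparable across patients of very different ventricular size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .masks import VolumeMask, compute_edv
from .segments import REGION_NAMES, SegmentMap

__all__ = [
    "RegionalVolumes",
    "RegionalDelta",
    "CohortSummary",
    "regional_volumes",
    "global_delta",
    "regional_delta",
    "aggregate_cohort",
    "per_patient_table",
    "cohort_table",
    "table1_report",
]

N_REGIONS = 14


@dataclass(frozen=True)
class RegionalVolumes:
    """Per-region and total EDV of one segmentation, millilitres."""

    per_region: np.ndarray
    total: float
    modality: str = ""
    patient: str = ""
    expert: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.per_region, dtype=float).reshape(N_REGIONS)
        object.__setattr__(self, "per_region", v)
        if np.any(v < 0):
            raise ValueError("regional volumes must be non-negative")
        if abs(v.sum() - self.total) > 1e-9:
            raise ValueError(
                f"regional volumes sum to {v.sum():.12g} ml but total is {self.total:.12g} ml")


@dataclass(frozen=True)
class RegionalDelta:
    """Global ΔEDV (ml) and the 14 regional fractions (percent of CMR EDV)."""

    global_delta_ml: float
    per_region_pct: np.ndarray
    cmr_total_ml: float
    patient: str = ""
    expert: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.per_region_pct, dtype=float).reshape(N_REGIONS)
        object.__setattr__(self, "per_region_pct", v)
        expected = 100.0 * self.global_delta_ml / self.cmr_total_ml
        if abs(v.sum() - expected) > 1e-6:
            raise ValueError("regional fractions do not sum to the global relative difference")


@dataclass(frozen=True)
class CohortSummary:
    """Cross-patient means and SDs of the regional fractions (percent)."""

    region_mean_pct: np.ndarray
    region_sd_pct: np.ndarray
    n_patients: int
    #: patient id -> (mean, sd) of the global ΔEDV across experts, ml
    patient_global: dict = field(default_factory=dict)


def regional_volumes(segmap: SegmentMap, mask: Optional[VolumeMask] = None,
                     modality: str = "", patient: str = "",
                     expert: str = "") -> RegionalVolumes:
    """Per-region volumes from a segment map (voxel counts x voxel volume).

    When the source mask is supplied its grid and total volume are checked
    against the segment map, guarding against mixed-up inputs.
    """
    vols = segmap.region_volumes_ml()
    total = float(vols.sum())
    if mask is not None:
        if mask.data.shape != segmap.labels.shape:
            raise ValueError("segment map and mask are on different grids")
        if abs(compute_edv(mask) - total) > 1e-9:
            raise ValueError("segment map does not partition the mask foreground")
    return RegionalVolumes(vols, total, modality=modality, patient=patient, expert=expert)


def global_delta(echo: RegionalVolumes, cmr: RegionalVolumes) -> float:
    """ΔEDV = EDV_echo − EDV_CMR, millilitres."""
    return echo.total - cmr.total


def regional_delta(echo: RegionalVolumes, cmr: RegionalVolumes,
                   patient: str = "", expert: str = "") -> RegionalDelta:
    """Regional volume differences as percent of the total CMR volume."""
    if cmr.total <= 0:
        raise ValueError("CMR total volume is zero: regional fractions undefined")
    pct = 100.0 * (echo.per_region - cmr.per_region) / cmr.total
    return RegionalDelta(global_delta(echo, cmr), pct, cmr.total,
                         patient=patient or echo.patient, expert=expert)


def aggregate_cohort(deltas_by_patient: Mapping[str, Sequence[RegionalDelta]]) -> CohortSummary:
    """Cohort statistics across patients (and experts within patients).

    Each patient contributes one regional-fraction vector: the mean over
    that patient's deltas (a single consensus delta, or per-expert deltas).
    Means and sample SDs (n−1) are then taken across patients. With a single
    patient the SD is reported as 0 and flagged with a warning.
    """
    if len(deltas_by_patient) == 0:
        raise ValueError("cohort aggregation needs at least one patient")
    patient_vecs = []
    patient_global = {}
    for pid, deltas in deltas_by_patient.items():
        deltas = list(deltas)
        if not deltas:
            raise ValueError(f"patient {pid!r} has no deltas")
        mat = np.stack([d.per_region_pct for d in deltas])
        patient_vecs.append(mat.mean(axis=0))
        globals_ml = np.array([d.global_delta_ml for d in deltas])
        sd = float(globals_ml.std(ddof=1)) if len(globals_ml) > 1 else 0.0
        patient_global[pid] = (float(globals_ml.mean()), sd)

    stack = np.stack(patient_vecs)
    mean = stack.mean(axis=0)
    if len(stack) > 1:
        sd = stack.std(axis=0, ddof=1)
    else:
        warnings.warn("single-patient cohort: SD reported as 0", stacklevel=2)
        sd = np.zeros(N_REGIONS)
    return CohortSummary(mean, sd, len(stack), patient_global)


# --------------------------------------------------------------------------
# Tabular outputs
# --------------------------------------------------------------------------

def per_patient_table(echo: RegionalVolumes, cmr: RegionalVolumes,
                      delta: RegionalDelta) -> pd.DataFrame:
    """Per-region table for one patient: echo ml, CMR ml, fraction %."""
    return pd.DataFrame({
        "patient": delta.patient,
        "region": np.arange(1, N_REGIONS + 1),
        "name": [REGION_NAMES[r] for r in range(1, N_REGIONS + 1)],
        "echo_ml": echo.per_region,
        "cmr_ml": cmr.per_region,
        "delta_pct": np.round(delta.per_region_pct, 1),
    })


def cohort_table(summary: CohortSummary) -> pd.DataFrame:
    return pd.DataFrame({
        "region": np.arange(1, N_REGIONS + 1),
        "name": [REGION_NAMES[r] for r in range(1, N_REGIONS + 1)],
        "mean_pct": np.round(summary.region_mean_pct, 1),
        "sd_pct": np.round(summary.region_sd_pct, 1),
    })


def table1_report(volumes: Sequence[RegionalVolumes]) -> str:
    """Per-patient global EDV report: echo, CMR, and difference, mean ± SD.

    Expects per-expert volumes tagged with patient/modality/expert; the
    difference column pairs echo and CMR volumes by expert id.
    """
    rows = []
    patients = sorted({v.patient for v in volumes})
    for pid in patients:
        echo = {v.expert: v.total for v in volumes if v.patient == pid and v.modality == "echo"}
        cmr = {v.expert: v.total for v in volumes if v.patient == pid and v.modality == "cmr"}
        shared = sorted(set(echo) & set(cmr))
        diffs = np.array([echo[e] - cmr[e] for e in shared])
        ev = np.array(list(echo.values()))
        cv = np.array(list(cmr.values()))

        def ms(a: np.ndarray) -> str:
            if len(a) == 0:
                return "n/a"
            sd = a.std(ddof=1) if len(a) > 1 else 0.0
            return f"{a.mean():.2f} ± {sd:.2f}"

        rows.append((pid, ms(ev), ms(cv), ms(diffs)))

    widths = [max(len(str(r[i])) for r in rows + [("Patient", "Echo", "CMR", "Echo-CMR")])
              for i in range(4)]
    header = ("Patient", "Echo", "CMR", "Echo-CMR")
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths)),
             "  ".join("-" * w for w in widths)]
    lines += ["  ".join(str(c).ljust(w) for c, w in zip(r, widths)) for r in rows]
    lines.append("")
    lines.append("End-diastolic volumes in millilitres, mean ± SD over experts.")
    return "\n".join(lines) + "\n"
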