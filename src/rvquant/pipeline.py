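"""End-to-end analysis pipeline over a cohort dataset directory.

Per patient: combine the expert masks of each modality by the strict-majority
consensus, register the echo landmarks onto the CMR landmarks, resample the
consensus echo mask into CMR space, divide both masks into the 14 segments
using the CMR landmark frame, and compute the global and regional volume
differences. Cohort statistics, tables, and figures follow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (RegionalDelta, RegionalVolumes, aggregate_cohort,
                       cohort_table, global_delta, per_patient_table,
                       regional_delta, regional_volumes, table1_report)
from .config import RunConfig
from .geometry import (LandmarkSet, RigidTransform, fit_rigid_transform,
                       landmark_residual, read_landmarks)
from .masks import VolumeMask, compute_edv, consensus_mask, read_mask, resample_mask, write_mask
from .plots import BullseyeSpec, render_bar_summary, render_bullseye, render_overlay
from .segments import build_axis_frame, divide_segments

logger = logging.getLogger(__name__)

__all__ = ["register_pair", "analyze_patient", "analyze_dataset", "PatientResult"]


@dataclass
class PatientResult:
    patient: str
    echo_volumes: RegionalVolumes
    cmr_volumes: RegionalVolumes
    delta: RegionalDelta
    transform: RigidTransform
    residual_rms_mm: float
    expert_deltas: list


def register_pair(echo_landmarks: LandmarkSet, cmr_landmarks: LandmarkSet,
                  echo_mask: VolumeMask, cmr_mask: VolumeMask):
    """Landmark registration of an echo mask into CMR space.

    Returns (aligned echo mask on the CMR grid, echo→CMR transform,
    residual report). CMR is the fixed image throughout.
    """
    transform = fit_rigid_transform(echo_landmarks, cmr_landmarks)
    residual = landmark_residual(echo_landmarks, cmr_landmarks, transform)
    aligned = resample_mask(echo_mask, transform, cmr_mask)
    return aligned, transform, residual


def _expert_masks(pdir: Path, modality: str):
    files = sorted(pdir.glob(f"{modality}_expert*_mask.*"))
    if files:
        return [read_mask(f) for f in files], [f.stem.split("_")[1] for f in files]
    single = list(pdir.glob(f"{modality}_mask.*"))
    if single:
        return [read_mask(single[0])], ["expert1"]
    raise FileNotFoundError(f"no {modality} masks under {pdir}")


def analyze_patient(pdir: Path, config: RunConfig,
                    out_dir: Optional[Path] = None) -> PatientResult:
    pdir = Path(pdir)
    pid = pdir.name
    cmr_lm = read_landmarks(pdir / "cmr_landmarks.json")
    echo_lm = read_landmarks(pdir / "echo_landmarks.json")
    cmr_masks, _ = _expert_masks(pdir, "cmr")
    echo_masks, expert_ids = _expert_masks(pdir, "echo")

    cmr_cons = consensus_mask(cmr_masks)
    echo_cons = consensus_mask(echo_masks)

    aligned, transform, residual = register_pair(echo_lm, cmr_lm, echo_cons, cmr_cons)
    logger.info("%s: registered echo→CMR, residual rms %.3f mm", pid, residual.rms)

    frame = build_axis_frame(cmr_lm, flip_chirality=config.flip_chirality)
    cmr_map = divide_segments(cmr_cons, frame, config.layer_bounds)
    echo_map = divide_segments(aligned, frame, config.layer_bounds)

    cmr_vol = regional_volumes(cmr_map, cmr_cons, modality="cmr", patient=pid)
    echo_vol = regional_volumes(echo_map, aligned, modality="echo", patient=pid)
    delta = regional_delta(echo_vol, cmr_vol, patient=pid)

    expert_deltas = []
    if config.consensus_mode == "per_expert" and len(echo_masks) == len(cmr_masks):
        for eid, e_mask, c_mask in zip(expert_ids, echo_masks, cmr_masks):
            e_aligned = resample_mask(e_mask, transform, cmr_cons)
            e_map = divide_segments(e_aligned, frame, config.layer_bounds)
            c_map = divide_segments(c_mask, frame, config.layer_bounds)
            ev = regional_volumes(e_map, modality="echo", patient=pid, expert=eid)
            cv = regional_volumes(c_map, modality="cmr", patient=pid, expert=eid)
            expert_deltas.append(regional_delta(ev, cv, patient=pid, expert=eid))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(out_dir / f"{pid}_transform.txt", transform.matrix4(), fmt="%.12g",
                   header="echo-to-CMR rigid transform, homogeneous 4x4, mm")
        write_mask(aligned, out_dir / f"{pid}_echo_aligned.nii.gz")
        (out_dir / f"{pid}_residual.json").write_text(json.dumps({
            "per_landmark_mm": residual.per_landmark_distance,
            "rms_mm": residual.rms, "max_mm": residual.max}, indent=2) + "\n")
        spec = BullseyeSpec(cmap=config.colormap, dpi=config.figure_dpi)
        render_bullseye(delta.per_region_pct, out_dir / f"{pid}_bullseye.png",
                        spec=spec, title=pid)
        render_overlay(cmr_cons, aligned, frame, n_planes=config.n_overlay_planes,
                       path_prefix=out_dir / f"{pid}_overlay", dpi=config.figure_dpi)

    return PatientResult(pid, echo_vol, cmr_vol, delta, transform,
                         residual.rms, expert_deltas)


def analyze_dataset(dataset_dir, out_dir, config: Optional[RunConfig] = None) -> dict:
    """Run the full pipeline on a dataset directory; write tables and figures.

    Patients failing to load are skipped with a warning. Returns a summary
    dict (per-patient deltas, cohort statistics, output paths).
    """
    config = config or RunConfig()
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    patient_dirs = sorted(d for d in dataset_dir.iterdir()
                          if d.is_dir() and d.name.startswith("patient"))
    if not patient_dirs:
        raise FileNotFoundError(f"no patient_* directories under {dataset_dir}")

    results: list[PatientResult] = []
    for pdir in patient_dirs:
        try:
            results.append(analyze_patient(pdir, config, out_dir=out_dir))
        except (FileNotFoundError, ValueError) as exc:
            logger.warning("skipping %s: %s", pdir.name, exc)
    if not results:
        raise RuntimeError("no patient could be analyzed")

    tables = [per_patient_table(r.echo_volumes, r.cmr_volumes, r.delta) for r in results]
    pd.concat(tables, ignore_index=True).to_csv(out_dir / "regional_per_patient.csv",
                                                index=False)

    if config.consensus_mode == "per_expert":
        deltas = {r.patient: (r.expert_deltas or [r.delta]) for r in results}
    else:
        deltas = {r.patient: [r.delta] for r in results}
    summary = aggregate_cohort(deltas)
    cohort_table(summary).to_csv(out_dir / "cohort_summary.csv", index=False)
    render_bar_summary(summary, out_dir / "cohort_bars.png", dpi=config.figure_dpi)

    # Table-1-style per-expert global volume report.
    expert_volumes = []
    for pdir in patient_dirs:
        pid = pdir.name
        for modality in ("echo", "cmr"):
            try:
                masks, expert_ids = _expert_masks(pdir, modality)
            except FileNotFoundError:
                continue
            for eid, m in zip(expert_ids, masks):
                vol = compute_edv(m)
                expert_volumes.append(RegionalVolumes(
                    np.concatenate([[vol], np.zeros(13)]), vol,
                    modality=modality, patient=pid, expert=eid))
    report = table1_report(expert_volumes)
    (out_dir / "global_volumes.txt").write_text(report)

    import matplotlib
    provenance = {
        "rvquant_version": __version__,
        "numpy_version": np.__version__,
        "matplotlib_version": matplotlib.__version__,
        "config": config.to_dict(),
        "dataset": str(dataset_dir),
        "patients": [r.patient for r in results],
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    return {
        "patients": {r.patient: {
            "global_delta_ml": r.delta.global_delta_ml,
            "regional_pct": r.delta.per_region_pct.tolist(),
            "residual_rms_mm": r.residual_rms_mm,
        } for r in results},
        "cohort_mean_pct": summary.region_mean_pct.tolist(),
        "cohort_sd_pct": summary.region_sd_pct.tolist(),
        "out_dir": str(out_dir),
    }
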