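"""Readers and writers: TSV matrices, subject tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortGroundTruth
from .types import MotionTrace, TimecourseSet

__all__ = [
    "write_timecourses",
    "load_timecourses",
    "write_ground_truth",
    "write_fnc_matrix",
    "read_fnc_matrix",
    "write_windowed_fnc",
]


def write_timecourses(tcs: TimecourseSet, out_dir: str | Path) -> Path:
    """Write one TSV per subject plus subject table, motion, and a sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, mat in tcs.data.items():
        pd.DataFrame(mat, columns=tcs.component_labels).to_csv(
            out / f"{sid}_timecourses.tsv", sep="\t", index=False, float_format="%.17g"
        )
    tcs.subjects.to_csv(out / "subjects.tsv", sep="\t")
    for sid, mt in tcs.motion.items():
        cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        pd.DataFrame(
            np.hstack([mt.translations, mt.rotations]), columns=cols
        ).to_csv(out / f"{sid}_motion.tsv", sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "tr": tcs.tr,
        "n_components": tcs.n_components,
        "component_labels": tcs.component_labels,
        "subjects": tcs.subject_ids,
    }
    (out / "timecourses.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_timecourses(in_dir: str | Path, tr: float | None = None) -> TimecourseSet:
    """Load a directory written by :func:`write_timecourses`.

    Enforces dimensional consistency; a subject present in the table but
    without a matrix file (or vice versa) raises a named error.
    """
    d = Path(in_dir)
    sidecar_path = d / "timecourses.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if tr is None:
        tr = sidecar.get("tr")
    if tr is None:
        raise ValueError("TR not given and no sidecar found")
    table_path = d / "subjects.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"missing subject table {table_path}")
    subjects = pd.read_csv(table_path, sep="\t", index_col=0)
    subjects.index = subjects.index.astype(str)
    data: dict[str, np.ndarray] = {}
    shapes: dict[str, tuple] = {}
    for sid in subjects.index:
        f = d / f"{sid}_timecourses.tsv"
        if not f.exists():
            raise FileNotFoundError(f"subject {sid} in table but no matrix file {f.name}")
        df = pd.read_csv(f, sep="\t", float_precision="round_trip")
        data[sid] = df.values.astype(float)
        shapes[sid] = data[sid].shape
    stray = {p.name for p in d.glob("*_timecourses.tsv")} - {
        f"{sid}_timecourses.tsv" for sid in subjects.index
    }
    if stray:
        raise ValueError(f"matrix files without subject-table rows: {sorted(stray)}")
    t_counts = {s[0] for s in shapes.values()}
    if len(t_counts) > 1:
        bad = min(shapes, key=lambda s: shapes[s][0])
        raise ValueError(
            f"ragged time-point counts {sorted(t_counts)}; e.g. {bad}_timecourses.tsv"
        )
    motion: dict[str, MotionTrace] = {}
    for sid in subjects.index:
        f = d / f"{sid}_motion.tsv"
        if f.exists():
            m = pd.read_csv(f, sep="\t").values.astype(float)
            motion[sid] = MotionTrace(translations=m[:, :3], rotations=m[:, 3:])
    labels = sidecar.get("component_labels")
    return TimecourseSet(
        data=data, tr=float(tr), subjects=subjects, motion=motion, component_labels=labels
    )


def write_ground_truth(gt: CohortGroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "seed": gt.seed,
        "coupling": {
            "slope": gt.coupling.slope,
            "intercept": gt.coupling.intercept,
            "noise_sd": gt.coupling.noise_sd,
            "name": gt.coupling.name,
        },
        "transition_matrices": {
            g: tm.transition_matrix.tolist() for g, tm in gt.transition_models.items()
        },
        "true_nt": gt.true_nt,
        "true_path_length": gt.true_path_length,
        "state_sequences": {s: seq.tolist() for s, seq in gt.state_sequences.items()},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path


def write_fnc_matrix(z: np.ndarray, labels: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(z, index=labels, columns=labels).to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_fnc_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.values.astype(float), list(df.columns)


def write_windowed_fnc(wfnc, out_dir: str | Path) -> Path:
    """One TSV per subject (rows = windows, columns = pairs) + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, z in wfnc.z.items():
        pd.DataFrame(z, columns=wfnc.pair_names).to_csv(
            out / f"{sid}_wfnc.tsv", sep="\t", index=False, float_format="%.8g"
        )
    sidecar = {
        "window_width": wfnc.params.width,
        "gauss_alpha": wfnc.params.gauss_alpha,
        "step": wfnc.params.step,
        "tr": wfnc.tr,
        "window_starts": wfnc.window_starts.tolist(),
        "penalty": wfnc.penalty,
    }
    (out / "wfnc.json").write_text(json.dumps(sidecar, indent=2))
    return out
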