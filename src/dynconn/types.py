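"""Shared containers for time courses, motion traces, and statistical results.

Component time courses are kept as plain ``numpy`` arrays (time points x
components) grouped in a :class:`TimecourseSet` together with the repetition
time, subject metadata and per-subject motion traces.  Connectivity values are
always Fisher-z transformed correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "TimecourseSet",
    "StatResult",
    "pair_labels",
    "vec_upper",
    "mat_from_vec",
]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters sampled once per TR.

    Translations are in mm, rotations in degrees.  Rotations are converted to
    arc length on a sphere of ``head_radius_mm`` (Power-style convention) for
    framewise displacement (FD) and root-mean-square (RMS) summaries.
    """

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3) deg
    head_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValueError("translations must be (T, 3)")
        if self.rotations.shape != self.translations.shape:
            raise ValueError("rotations must match translations shape")

    @property
    def n_timepoints(self) -> int:
        return self.translations.shape[0]

    def params_mm(self) -> np.ndarray:
        """All six parameters on a common mm scale, shape (T, 6)."""
        rot_mm = np.deg2rad(self.rotations) * self.head_radius_mm
        return np.hstack([self.translations, rot_mm])

    def framewise_displacement(self) -> np.ndarray:
        """Per-TR FD: sum of absolute frame-to-frame parameter changes (mm).

        FD at the first TR is defined as 0.
        """
        p = self.params_mm()
        fd = np.zeros(p.shape[0])
        fd[1:] = np.abs(np.diff(p, axis=0)).sum(axis=1)
        return fd

    @property
    def mean_fd(self) -> float:
        return float(self.framewise_displacement().mean())

    @property
    def rms_motion(self) -> float:
        """RMS of the six motion parameters (mm, rotations on the sphere)."""
        return float(np.sqrt(np.mean(self.params_mm() ** 2)))

    @property
    def max_translation(self) -> float:
        return float(np.abs(self.translations).max())

    @property
    def max_rotation(self) -> float:
        return float(np.abs(self.rotations).max())


@dataclass
class TimecourseSet:
    """Multi-subject component time courses plus metadata.

    ``data`` maps subject id -> (T x C) matrix. All subjects must share the
    component count and TR. ``subjects`` is indexed by subject id and carries
    at least a ``group`` column; clinical/motion summary columns are free-form.
    """

    data: dict[str, np.ndarray]
    tr: float
    subjects: pd.DataFrame
    motion: dict[str, MotionTrace] = field(default_factory=dict)
    component_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.data:
            raise ValueError("empty TimecourseSet")
        shapes = {k: np.asarray(v).shape for k, v in self.data.items()}
        ncomp = {s[1] for s in shapes.values()}
        if len(ncomp) != 1:
            raise ValueError(f"inconsistent component counts: {sorted(ncomp)}")
        for sid, arr in self.data.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2 or a.shape[0] < 2:
                raise ValueError(f"subject {sid}: need a 2-D matrix with >= 2 time points")
            if not np.isfinite(a).all():
                raise ValueError(f"subject {sid}: non-finite values in time courses")
            self.data[sid] = a
        missing = set(self.data) - set(self.subjects.index)
        extra = set(self.subjects.index) - set(self.data)
        if missing or extra:
            raise ValueError(
                f"subject table mismatch: missing rows for {sorted(missing)}, "
                f"rows without data for {sorted(extra)}"
            )
        c = self.n_components
        if self.component_labels is None:
            self.component_labels = [f"C{i + 1}" for i in range(c)]
        elif len(self.component_labels) != c:
            raise ValueError("component_labels length mismatch")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_components(self) -> int:
        return next(iter(self.data.values())).shape[1]

    def groups(self) -> pd.Series:
        return self.subjects["group"]

    def subset(self, ids: Sequence[str]) -> "TimecourseSet":
        ids = list(ids)
        return TimecourseSet(
            data={s: self.data[s] for s in ids},
            tr=self.tr,
            subjects=self.subjects.loc[ids].copy(),
            motion={s: self.motion[s] for s in ids if s in self.motion},
            component_labels=list(self.component_labels),
        )


@dataclass
class StatResult:
    """One statistical test: statistic, p-values, and bookkeeping."""

    test: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    corrected_p: float | None = None
    correction: str | None = None
    direction: int = 0  # sign of the effect (group A minus group B, or r)
    n: tuple | int | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.corrected_p is not None:
            if self.corrected_p < self.p_value - 1e-12:
                raise ValueError("corrected p must be >= raw p")
            if self.corrected_p > 1:
                raise ValueError("corrected p must be <= 1")


def pair_labels(labels: Sequence[str]) -> list[str]:
    """Upper-triangle pair labels 'A|B' in row-major (i<j) order."""
    out = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            out.append(f"{labels[i]}|{labels[j]}")
    return out


def vec_upper(mat: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix (i<j, row-major)."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mat_from_vec(vec: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vec_upper` for symmetric matrices."""
    out = np.full((n, n), diag, dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out
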