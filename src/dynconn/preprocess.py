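"""Time-course conditioning: QC exclusion, detrending, despiking, filtering.

The conditioning pipeline mirrors standard component time-course hygiene for
connectivity analyses: subjects with excessive head motion are dropped, then
each component series is detrended (mean, slope, half-cycle and full-cycle
sine/cosine), despiked with a MAD-based soft-compression rule, and low-pass
filtered with a zero-phase Butterworth filter.  A multitaper (DPSS) spectrum
estimator is provided for spectral features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .types import TimecourseSet

__all__ = [
    "PreprocessParams",
    "qc_exclude",
    "detrend_basis",
    "detrend_timecourse",
    "mad_sigma",
    "despike_timecourse",
    "lowpass_filter",
    "multitaper_spectrum",
    "condition_timecourses",
    "preprocess_set",
]


@dataclass
class PreprocessParams:
    """Conditioning parameters with the study's defaults.

    QC thresholds are maxima over the scan (3 mm translation, 3 deg rotation);
    the low-pass filter is a fifth-order Butterworth at 0.15 Hz applied
    forward-backward; despiking compresses detrend residuals beyond
    ``despike_c1`` MAD units, saturating at ``despike_c2``.
    """

    max_translation: float = 3.0  # mm
    max_rotation: float = 3.0  # deg
    despike_c1: float = 2.5
    despike_c2: float = 4.0
    filter_order: int = 5
    filter_cutoff: float = 0.15  # Hz
    taper_time_bandwidth: float = 3.0
    taper_count: int = 5

    def __post_init__(self) -> None:
        if not self.despike_c2 > self.despike_c1 > 0:
            raise ValueError("need despike_c2 > despike_c1 > 0")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.taper_count > 2 * self.taper_time_bandwidth - 1:
            raise ValueError(
                f"taper count {self.taper_count} exceeds 2*NW-1 = "
                f"{2 * self.taper_time_bandwidth - 1:g}"
            )


def qc_exclude(
    tcs: TimecourseSet, params: PreprocessParams | None = None
) -> tuple[TimecourseSet, list[dict]]:
    """Drop subjects whose head motion exceeds the QC ceilings.

    Exclusion requires a maximum absolute translation strictly greater than
    ``max_translation`` (mm) or rotation strictly greater than
    ``max_rotation`` (deg); a value exactly at the ceiling is kept.  Subjects
    with no motion trace are flagged in the report and excluded rather than
    silently kept.
    """
    params = params or PreprocessParams()
    report: list[dict] = []
    kept: list[str] = []
    for sid in tcs.subject_ids:
        mt = tcs.motion.get(sid)
        if mt is None:
            report.append({"subject": sid, "reason": "missing motion trace"})
            continue
        if mt.max_translation > params.max_translation:
            report.append(
                {
                    "subject": sid,
                    "reason": "translation",
                    "value_mm": mt.max_translation,
                    "threshold_mm": params.max_translation,
                }
            )
        elif mt.max_rotation > params.max_rotation:
            report.append(
                {
                    "subject": sid,
                    "reason": "rotation",
                    "value_deg": mt.max_rotation,
                    "threshold_deg": params.max_rotation,
                }
            )
        else:
            kept.append(sid)
    if not kept:
        raise ValueError("QC excluded every subject")
    return tcs.subset(kept), report


def detrend_basis(n_timepoints: int) -> np.ndarray:
    """Detrend regressors: intercept, slope, half- and full-cycle sin/cos.

    The periodic regressors complete one half cycle and one full cycle over
    the record, the trend terms a smooth-fit basis for despiking as well.
    """
    if n_timepoints < 7:
        raise ValueError("need at least 7 time points (6 regressors + 1)")
    t = np.arange(n_timepoints) / n_timepoints
    return np.column_stack(
        [
            np.ones(n_timepoints),
            t,
            np.sin(np.pi * t),
            np.cos(np.pi * t),
            np.sin(2 * np.pi * t),
            np.cos(2 * np.pi * t),
        ]
    )


def _smooth_fit(tc: np.ndarray) -> np.ndarray:
    x = detrend_basis(tc.shape[0])
    beta, *_ = np.linalg.lstsq(x, tc, rcond=None)
    return x @ beta


def detrend_timecourse(tc: np.ndarray) -> np.ndarray:
    """Least-squares residual after removing mean, slope and slow sinusoids."""
    tc = np.asarray(tc, dtype=float)
    return tc - _smooth_fit(tc)


def mad_sigma(x: np.ndarray) -> float:
    """Robust scale: 1.4826 * median absolute deviation from the median."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def despike_timecourse(tc: np.ndarray, c1: float = 2.5, c2: float = 4.0) -> np.ndarray:
    """Compress large excursions from a smooth fit (3dDespike-style).

    Residuals from the detrend-basis fit with magnitude <= ``c1`` MAD-sigma
    units pass unchanged; larger residuals are soft-clipped to
    ``c1 + (c2 - c1) * tanh((s - c1)/(c2 - c1))`` MAD units (``s`` the
    residual magnitude in MAD units), sign preserved, then re-added to the
    smooth fit.  A series with zero residual MAD is returned unchanged.
    """
    if not c2 > c1 > 0:
        raise ValueError("need c2 > c1 > 0")
    tc = np.asarray(tc, dtype=float)
    if tc.shape[0] < 8:
        raise ValueError("need at least 8 time points to despike")
    fit = _smooth_fit(tc)
    resid = tc - fit
    sigma = mad_sigma(resid)
    if sigma == 0:
        return tc.copy()
    s = np.abs(resid) / sigma
    out_units = np.where(s <= c1, s, c1 + (c2 - c1) * np.tanh((s - c1) / (c2 - c1)))
    return fit + np.sign(resid) * out_units * sigma


def lowpass_filter(tc: np.ndarray, tr: float, order: int = 5, cutoff: float = 0.15) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain 1)."""
    nyquist = 0.5 / tr
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff, btype="low", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(tc, dtype=float))


def multitaper_spectrum(
    tc: np.ndarray, tr: float, time_bandwidth: float = 3.0, n_tapers: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper (DPSS) power spectrum of one series.

    Averages periodograms over unit-energy discrete-prolate-spheroidal
    tapers.  The one-sided power values sum approximately to the series
    variance (Parseval); frequencies are in Hz.
    """
    tc = np.asarray(tc, dtype=float)
    t = tc.shape[0]
    max_tapers = int(2 * time_bandwidth - 1)
    if n_tapers > max_tapers:
        raise ValueError(f"n_tapers {n_tapers} exceeds 2*NW-1 = {max_tapers}")
    if n_tapers < 1:
        raise ValueError("need at least one taper")
    tapers = signal.windows.dpss(t, time_bandwidth, Kmax=n_tapers)  # rows unit-energy
    x = tc - tc.mean()
    spec = np.zeros(t // 2 + 1)
    for w in tapers:
        f = np.fft.rfft(w * x)
        p = np.abs(f) ** 2 / t
        p[1:] *= 2.0
        if t % 2 == 0:
            p[-1] /= 2.0
        spec += p
    spec /= n_tapers
    freqs = np.fft.rfftfreq(t, d=tr)
    return freqs, spec


def condition_timecourses(
    mat: np.ndarray, tr: float, params: PreprocessParams | None = None
) -> np.ndarray:
    """Detrend -> despike -> low-pass each column of a (T x C) matrix."""
    params = params or PreprocessParams()
    mat = np.asarray(mat, dtype=float)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        x = detrend_timecourse(mat[:, j])
        x = despike_timecourse(x, params.despike_c1, params.despike_c2)
        out[:, j] = lowpass_filter(x, tr, params.filter_order, params.filter_cutoff)
    return out


def preprocess_set(
    tcs: TimecourseSet, params: PreprocessParams | None = None, qc: bool = True
) -> tuple[TimecourseSet, list[dict]]:
    """QC-exclude then condition every subject's time courses."""
    params = params or PreprocessParams()
    report: list[dict] = []
    if qc:
        if not tcs.motion:
            warnings.warn("no motion traces available; skipping QC exclusion")
        else:
            tcs, report = qc_exclude(tcs, params)
    conditioned = {
        sid: condition_timecourses(mat, tcs.tr, params) for sid, mat in tcs.data.items()
    }
    out = replace(tcs, data=conditioned)
    return out, report
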