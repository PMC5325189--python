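"""Cerebrovascular indices from baselined average pulse waveforms.

Two indices are computed per channel/voxel:

* **pulse amplitude** -- mean percent-change intensity over the systolic
  window (384--538 ms post R wave), a proxy for cerebral pulse pressure;
* **arterial compliance** -- the area under the diastolic section of the
  pulse, after normalizing time (systolic peak -> diastolic reference mapped
  to [0, 1]) and amplitude (systolic peak -> 1, diastolic reference -> 0),
  minus the constant 0.5.  The constant compares the measured area against a
  triangle, i.e. a hypothetical straight-line fall-off: 0 means a straight
  oblique decay, +0.5 a decay that stays at the systolic level for the whole
  diastole, and negative values a fast convex (stiff-artery) decay.

Compliance is therefore invariant to any positive affine transform of the
waveform and to uniform time dilation, and is decoupled from amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateWaveformError, EmptyRoiError, InvertedWaveformError
from .optics import PulseWaveform

SYSTOLIC_WINDOW_MS = (384.0, 538.0)
DIASTOLE_SEARCH_CAP_MS = 900.0
COMPLIANCE_CONSTANT = 0.5

QC_DEGENERATE = "degenerate"
QC_YNORM_RANGE = "ynorm_out_of_range"
QC_LOW_EPOCHS = "low_epochs"


@dataclass
class NormalizedDiastole:
    """Diastolic segment mapped onto the unit square.

    ``t_norm`` runs from 0 (systolic peak) to 1 (diastolic reference);
    ``y_norm`` is 1 at the systolic peak and 0 at the diastolic reference.
    """

    t_norm: np.ndarray
    y_norm: np.ndarray

    def __post_init__(self) -> None:
        self.t_norm = np.asarray(self.t_norm, dtype=float)
        self.y_norm = np.asarray(self.y_norm, dtype=float)
        if self.t_norm.shape != self.y_norm.shape:
            raise ValueError("t_norm and y_norm must have the same shape")
        if self.t_norm.size >= 2 and np.any(np.diff(self.t_norm) <= 0):
            raise ValueError("t_norm must be strictly increasing")


def pulse_amplitude(
    w: PulseWaveform, window_ms: tuple[float, float] = SYSTOLIC_WINDOW_MS
) -> float:
    """Mean baselined percent-change intensity over the systolic window."""
    in_win = (w.time_ms >= window_ms[0]) & (w.time_ms <= window_ms[1])
    if not in_win.any():
        raise ValueError(f"waveform grid does not cover {window_ms} ms")
    return float(w.y[in_win].mean())


def locate_peaks(
    w: PulseWaveform,
    systolic_window_ms: tuple[float, float] = SYSTOLIC_WINDOW_MS,
    diastole_cap_ms: float = DIASTOLE_SEARCH_CAP_MS,
) -> tuple[float, float]:
    """Annotate the systolic peak and the diastolic reference.

    Systole is the argmax of ``y`` inside the systolic window; the diastolic
    reference is the minimum between the systolic peak and ``diastole_cap_ms``
    (or the end of the grid, whichever comes first).  Ties break to the
    earliest sample.
    """
    sys_win = (w.time_ms >= systolic_window_ms[0]) & (w.time_ms <= systolic_window_ms[1])
    if not sys_win.any():
        raise ValueError(f"waveform grid does not cover {systolic_window_ms} ms")
    y_sys_region = w.y[sys_win]
    if not np.all(np.isfinite(y_sys_region)):
        raise ValueError("non-finite values in systolic search region")
    if np.ptp(w.y) == 0:
        raise DegenerateWaveformError("flat waveform: no unique systolic peak")
    sys_idx = np.flatnonzero(sys_win)[int(np.argmax(y_sys_region))]
    sys_ms = float(w.time_ms[sys_idx])

    dia_region = (w.time_ms > sys_ms) & (w.time_ms <= diastole_cap_ms)
    if not dia_region.any():
        raise DegenerateWaveformError("no samples after the systolic peak")
    if not np.all(np.isfinite(w.y[dia_region])):
        raise ValueError("non-finite values in diastolic search region")
    dia_idx = np.flatnonzero(dia_region)[int(np.argmin(w.y[dia_region]))]
    dia_ms = float(w.time_ms[dia_idx])
    w.annotations.update(
        {
            "systole_time_ms": sys_ms,
            "systole_value": float(w.y[sys_idx]),
            "diastole_time_ms": dia_ms,
            "diastole_value": float(w.y[dia_idx]),
        }
    )
    return sys_ms, dia_ms


def normalize_diastole(
    w: PulseWaveform, peaks: tuple[float, float] | None = None
) -> NormalizedDiastole:
    """Map the diastolic segment onto the unit square (affine in t and y)."""
    if peaks is None:
        peaks = locate_peaks(w)
    sys_ms, dia_ms = peaks
    if not sys_ms < dia_ms:
        raise ValueError("systolic peak must precede the diastolic reference")
    seg = (w.time_ms >= sys_ms) & (w.time_ms <= dia_ms)
    t = w.time_ms[seg]
    y = w.y[seg]
    y_sys, y_dia = y[0], y[-1]
    if y_sys <= y_dia:
        raise InvertedWaveformError(
            "inverted waveform: systolic value does not exceed diastolic value"
        )
    return NormalizedDiastole(
        t_norm=(t - sys_ms) / (dia_ms - sys_ms),
        y_norm=(y - y_dia) / (y_sys - y_dia),
    )


def arterial_compliance(nd: NormalizedDiastole) -> float:
    """Trapezoidal area under the normalized diastole minus 0.5.

    Lies in [-0.5, +0.5] whenever ``y_norm`` stays inside [0, 1]; segments
    exiting that range (noise) are integrated as-is and should be flagged by
    the caller (see :func:`indices_per_unit`).
    """
    if nd.t_norm.size < 3:
        raise ValueError("normalized diastole needs at least 3 samples")
    return float(np.trapezoid(nd.y_norm, nd.t_norm) - COMPLIANCE_CONSTANT)


def ynorm_in_range(nd: NormalizedDiastole, tol: float = 1e-9) -> bool:
    return bool(np.all(nd.y_norm >= -tol) and np.all(nd.y_norm <= 1 + tol))


def indices_per_unit(
    waveforms: list[PulseWaveform],
    amplitude_window_ms: tuple[float, float] = SYSTOLIC_WINDOW_MS,
    diastole_cap_ms: float = DIASTOLE_SEARCH_CAP_MS,
) -> pd.DataFrame:
    """Compute amplitude and compliance for every waveform.

    Degenerate waveforms yield NaN indices with a ``degenerate`` QC flag
    rather than aborting the whole subject.
    """
    rows = []
    for w in waveforms:
        flags = set(w.flags)
        amp = comp = sys_ms = dia_ms = np.nan
        try:
            amp = pulse_amplitude(w, amplitude_window_ms)
            sys_ms, dia_ms = locate_peaks(w, amplitude_window_ms, diastole_cap_ms)
            nd = normalize_diastole(w, (sys_ms, dia_ms))
            if not ynorm_in_range(nd):
                flags.add(QC_YNORM_RANGE)
            comp = arterial_compliance(nd)
        except (DegenerateWaveformError, InvertedWaveformError, ValueError):
            flags.add(QC_DEGENERATE)
        rows.append(
            {
                "unit_id": w.unit_id,
                "amplitude_pct": amp,
                "compliance": comp,
                "systole_time_ms": sys_ms,
                "diastole_time_ms": dia_ms,
                "n_epochs": w.n_epochs,
                "qc_flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_index(
    indices: pd.DataFrame,
    column: str,
    members=None,
    exclude_flagged: bool = True,
) -> float:
    """Unweighted mean of a per-unit index over an ROI.

    ``members`` restricts to a set of unit ids (an ROI); ``exclude_flagged``
    drops units whose QC flags include ``degenerate`` or out-of-range
    normalized amplitudes.
    """
    df = indices
    if members is not None:
        members = set(members)
        df = df[df["unit_id"].isin(members)]
    if exclude_flagged:
        bad = df["qc_flags"].fillna("").str.contains(QC_DEGENERATE) | df[
            "qc_flags"
        ].fillna("").str.contains(QC_YNORM_RANGE)
        df = df[~bad]
    df = df[np.isfinite(df[column])]
    if len(df) == 0:
        raise EmptyRoiError(f"no usable units for aggregate of {column}")
    return float(df[column].mean())
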