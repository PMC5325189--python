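"""R-wave detection on a one-lead EKG trace.

The arterial pulse pipeline time-locks optical epochs to the R wave of the
QRS complex.  Detection is deliberately simple and transparent: zero-phase
band-pass (0.5--40 Hz), standardization of the filtered trace, peak search
above a z-score threshold with a physiological refractory window, and an
interbeat-interval (IBI) plausibility filter that discards candidates
producing implausibly short intervals (e.g. ectopic beats).  Every discarded
candidate carries exactly one reason code so that accepted + rejected
candidates always reconcile with the initial candidate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import NoBeatsDetectedError

#: reason codes attached to rejected beat candidates
REASON_SHORT_INTERVAL = "out_of_band_interval"
REASON_SUBTHRESHOLD = "sub_threshold"
REASON_MANUAL = "manual"


@dataclass
class EkgTrace:
    """One-lead EKG voltage series.

    Parameters
    ----------
    v : ndarray
        Voltage samples (arbitrary units).
    fs_hz : float
        Sampling rate, nominally 1000 Hz.
    subject_id : str
        Opaque subject label.
    """

    v: np.ndarray
    fs_hz: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("EKG trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.v.size / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.v.size) / self.fs_hz


@dataclass
class BeatSet:
    """Vetted R-wave times plus the audit trail of discarded candidates."""

    r_times_s: np.ndarray
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["time_s", "reason"])
    )
    n_candidates: int = 0
    manual_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        if self.r_times_s.size and np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("r_times_s must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.r_times_s.size)

    def validate_intervals(self, ibi_band_s: tuple[float, float]) -> None:
        """Raise if any consecutive interval falls below the plausibility band."""
        if self.n_beats >= 2:
            ibis = np.diff(self.r_times_s)
            if np.any(ibis < ibi_band_s[0]):
                raise ValueError(
                    f"interbeat interval below {ibi_band_s[0]} s after edit"
                )


def bandpass_ekg(
    trace: EkgTrace, low_hz: float = 0.5, high_hz: float = 40.0, order: int = 4
) -> EkgTrace:
    """Zero-phase Butterworth band-pass of the EKG trace.

    Forward-backward filtering (:func:`scipy.signal.filtfilt`) is used so the
    R-peak latency is not shifted by the filter's group delay.
    """
    nyq = trace.fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=trace.fs_hz, output="sos")
    v = signal.sosfiltfilt(sos, trace.v)
    return EkgTrace(v=v, fs_hz=trace.fs_hz, subject_id=trace.subject_id)


def detect_rwaves(
    trace: EkgTrace,
    z_threshold: float = 3.0,
    ibi_band_s: tuple[float, float] = (0.4, 2.0),
    refractory_s: float = 0.1,
) -> BeatSet:
    """Detect R-wave peaks on a band-passed trace.

    The trace is standardized (zero mean, unit SD), so detection is invariant
    to any positive gain applied to the raw voltage.  Local maxima above
    ``z_threshold`` and separated by at least ``refractory_s`` are taken as
    candidates; candidates creating interbeat intervals shorter than
    ``ibi_band_s[0]`` are iteratively removed (the lower-amplitude peak of the
    offending pair is dropped) and logged with a reason code.

    ``refractory_s`` only deduplicates multiple maxima of a single QRS
    complex; it is kept well below the IBI plausibility band so that closely
    spaced ectopic candidates are surfaced in the rejection log (with an
    interval reason code) rather than silently suppressed.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    sd = trace.v.std()
    if sd == 0:
        raise NoBeatsDetectedError("no beats detected: trace has zero variance")
    z = (trace.v - trace.v.mean()) / sd
    distance = max(1, int(round(refractory_s * trace.fs_hz)))
    idx, props = signal.find_peaks(z, height=z_threshold, distance=distance)
    if idx.size == 0:
        raise NoBeatsDetectedError(
            f"no beats detected: no peak exceeded z = {z_threshold}"
        )
    times = idx / trace.fs_hz
    heights = props["peak_heights"]
    n_candidates = int(idx.size)

    rejected_times: list[float] = []
    rejected_reasons: list[str] = []
    keep_t = list(times)
    keep_h = list(heights)
    # iteratively resolve short intervals, always dropping the weaker peak
    while len(keep_t) >= 2:
        ibis = np.diff(keep_t)
        bad = np.flatnonzero(ibis < ibi_band_s[0])
        if bad.size == 0:
            break
        i = int(bad[0])
        j = i if keep_h[i] < keep_h[i + 1] else i + 1
        rejected_times.append(keep_t.pop(j))
        rejected_reasons.append(REASON_SHORT_INTERVAL)
        keep_h.pop(j)

    rejected = pd.DataFrame({"time_s": rejected_times, "reason": rejected_reasons})
    return BeatSet(
        r_times_s=np.asarray(keep_t), rejected=rejected, n_candidates=n_candidates
    )


def override_beats(
    beats: BeatSet,
    add_times_s=(),
    drop_times_s=(),
    span_s: float | None = None,
    ibi_band_s: tuple[float, float] = (0.4, 2.0),
    match_tol_s: float = 0.005,
) -> BeatSet:
    """Apply manual edits (visual-inspection overrides) to a beat set.

    Additions already present (within ``match_tol_s``) are ignored, making the
    operation idempotent.  Edits that would violate strict ordering or create
    an interval below the plausibility band raise ``ValueError``.
    """
    times = list(beats.r_times_s)
    rejected = beats.rejected.copy()
    log = list(beats.manual_log)

    for t in sorted(drop_times_s):
        d = np.abs(np.asarray(times) - t)
        if d.size == 0 or d.min() > match_tol_s:
            raise ValueError(f"drop time {t} s matches no detected beat")
        j = int(d.argmin())
        dropped = times.pop(j)
        new_row = pd.DataFrame({"time_s": [dropped], "reason": [REASON_MANUAL]})
        rejected = (
            new_row if rejected.empty else pd.concat([rejected, new_row], ignore_index=True)
        )
        log.append(("drop", dropped))

    for t in sorted(add_times_s):
        if span_s is not None and not (0 <= t <= span_s):
            raise ValueError(f"added time {t} s outside recording span")
        if times and np.min(np.abs(np.asarray(times) - t)) <= match_tol_s:
            continue  # idempotent re-add
        times.append(t)
        log.append(("add", t))

    out = BeatSet(
        r_times_s=np.sort(np.asarray(times)),
        rejected=rejected,
        n_candidates=beats.n_candidates,
        manual_log=log,
    )
    out.validate_intervals(ibi_band_s)
    return out


def match_beats(
    detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float = 0.01
) -> dict:
    """Score detections against ground-truth beat times.

    Greedy one-to-one matching within ``tol_s``; returns counts plus
    sensitivity, positive predictive value and F1.
    """
    detected_s = np.asarray(detected_s, dtype=float)
    truth_s = np.asarray(truth_s, dtype=float)
    used = np.zeros(truth_s.size, dtype=bool)
    tp = 0
    for t in detected_s:
        d = np.abs(truth_s - t)
        d[used] = np.inf
        if d.size and d.min() <= tol_s:
            used[int(d.argmin())] = True
            tp += 1
    fp = detected_s.size - tp
    fn = truth_s.size - tp
    sens = tp / truth_s.size if truth_s.size else np.nan
    ppv = tp / detected_s.size if detected_s.size else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    return {"tp": tp, "fp": fp, "fn": fn, "sensitivity": sens, "ppv": ppv, "f1": f1}


def save_beats(path, beats: BeatSet) -> None:
    """Write accepted and rejected beat times to a single CSV with status codes."""
    acc = pd.DataFrame({"time_s": beats.r_times_s, "status": "accepted", "reason": ""})
    rej = beats.rejected.assign(status="rejected")[["time_s", "status", "reason"]]
    pd.concat([acc, rej], ignore_index=True).sort_values("time_s").to_csv(
        path, index=False, float_format="%.6f"
    )


def load_beats(path) -> BeatSet:
    df = pd.read_csv(path)
    acc = df[df["status"] == "accepted"]
    rej = df[df["status"] == "rejected"][["time_s", "reason"]].reset_index(drop=True)
    return BeatSet(
        r_times_s=np.sort(acc["time_s"].to_numpy()),
        rejected=rej,
        n_candidates=len(df),
    )
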