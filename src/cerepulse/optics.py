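"""Optical-channel conditioning and R-wave-locked epoch averaging.

Stages (in pipeline order): per-channel normalization to percent change about
the channel mean, artifact masking on the unfiltered percent-change series,
zero-phase 0.5--5 Hz band-pass, extraction of epochs time-locked to the EKG
R wave, resampling onto a common post-R grid at the native 25.6 ms spacing,
averaging, and baselining to the 128--256 ms post-R window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .ekg import BeatSet
from .errors import UnusableChannelError

NATIVE_FS_HZ = 39.0625
NATIVE_DT_MS = 1000.0 / NATIVE_FS_HZ  # 25.6 ms
BASELINE_WINDOW_MS = (128.0, 256.0)


@dataclass
class OpticalRecording:
    """Channels x samples AC-intensity matrix with channel labels."""

    ac: np.ndarray
    fs_hz: float = NATIVE_FS_HZ
    channel_ids: list = field(default_factory=list)
    block_id: str = "block1"
    montage_id: str = "m1"

    def __post_init__(self) -> None:
        self.ac = np.atleast_2d(np.asarray(self.ac, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.ac.shape[0] < 1:
            raise ValueError("recording must contain at least one channel")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.ac.shape[0])]
        if len(self.channel_ids) != self.ac.shape[0]:
            raise ValueError("channel_ids length does not match ac rows")

    @property
    def n_channels(self) -> int:
        return self.ac.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ac.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, ac: np.ndarray, channel_ids=None) -> "OpticalRecording":
        return OpticalRecording(
            ac=ac,
            fs_hz=self.fs_hz,
            channel_ids=list(self.channel_ids if channel_ids is None else channel_ids),
            block_id=self.block_id,
            montage_id=self.montage_id,
        )


@dataclass
class PulseWaveform:
    """R-wave-locked average pulse epoch for one channel or voxel.

    ``y`` is percent-change intensity on the fixed post-R grid ``time_ms``.
    """

    time_ms: np.ndarray
    y: np.ndarray
    n_epochs: int
    unit_id: str = ""
    baseline_window_ms: tuple = BASELINE_WINDOW_MS
    flags: set = field(default_factory=set)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.time_ms.shape != self.y.shape:
            raise ValueError("time_ms and y must have the same shape")


def normalize_channels(rec: OpticalRecording):
    """Express each channel as percent change about its own mean intensity.

    Channels with non-positive mean intensity cannot be normalized; they are
    dropped and reported in the exclusion log.

    Returns
    -------
    (OpticalRecording, list[str])
        Normalized recording and the ids of excluded channels.
    """
    means = rec.ac.mean(axis=1)
    good = means > 0
    excluded = [cid for cid, g in zip(rec.channel_ids, good) if not g]
    if not np.any(good):
        raise UnusableChannelError("all channels have non-positive mean intensity")
    ac = 100.0 * (rec.ac[good] / means[good, None] - 1.0)
    kept = [cid for cid, g in zip(rec.channel_ids, good) if g]
    return rec.copy_with(ac, channel_ids=kept), excluded


def bandpass_optical(
    rec: OpticalRecording, low_hz: float = 0.5, high_hz: float = 5.0, order: int = 4
) -> OpticalRecording:
    """Zero-phase Butterworth band-pass of every optical channel."""
    nyq = rec.fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.ac, axis=1))


def epoch_grid(epoch_span_ms: tuple[float, float] = (0.0, 1000.0)) -> np.ndarray:
    """Common post-R time grid at the native 25.6 ms spacing."""
    n = int(np.floor((epoch_span_ms[1] - epoch_span_ms[0]) / NATIVE_DT_MS)) + 1
    return epoch_span_ms[0] + NATIVE_DT_MS * np.arange(n)


def eligible_epochs(
    rec: OpticalRecording, beats: BeatSet, epoch_span_ms=(0.0, 1000.0)
) -> np.ndarray:
    """Boolean mask over beats: epoch fits in the recording and is not
    truncated by the next beat."""
    span_s = epoch_span_ms[1] / 1000.0
    t = beats.r_times_s
    ok = t + span_s <= rec.n_samples / rec.fs_hz
    ok &= t >= -epoch_span_ms[0] / 1000.0
    if t.size >= 2:
        next_ok = np.append(np.diff(t) >= span_s, True)
        ok &= next_ok
    return ok


def reject_artifacts(
    rec: OpticalRecording,
    beats: BeatSet,
    spike_z: float = 8.0,
    step_z: float = 6.0,
    epoch_span_ms: tuple[float, float] = (0.0, 1000.0),
    spike_floor_pct: float = 5.0,
) -> tuple[np.ndarray, dict]:
    """Mask epochs contaminated by motion artifacts.

    Runs on the *unfiltered* percent-change series so that boxcar baseline
    steps are still visible.  A sample is spike-flagged when its robust
    z-score (median/MAD) exceeds ``spike_z``; an epoch is masked when it
    overlaps any flagged sample, or when its own mean level deviates from the
    other epochs' by more than ``step_z`` robust SDs.

    ``spike_floor_pct`` is an absolute deviation floor (percent-change
    units) below which no sample is ever spike-flagged: motion artifacts in
    this modality sit an order of magnitude above the ~1% cardiac pulse, and
    without the floor the robust scale of a nearly noise-free recording
    collapses until the pulse itself looks like an outlier.

    Returns
    -------
    (keep, report)
        ``keep`` is a channels x beats boolean matrix (True = usable epoch);
        ``report`` logs counts and any channels left without usable epochs.
    """
    if spike_z <= 0 or step_z <= 0:
        raise ValueError("thresholds must be positive")
    elig = eligible_epochs(rec, beats, epoch_span_ms)
    n_ch, n_beats = rec.n_channels, beats.n_beats
    keep = np.tile(elig, (n_ch, 1))

    med = np.median(rec.ac, axis=1, keepdims=True)
    mad = np.median(np.abs(rec.ac - med), axis=1, keepdims=True)
    scale = 1.4826 * np.where(mad > 0, mad, np.inf)
    dev = np.abs(rec.ac - med)
    bad_sample = (dev / scale > spike_z) & (dev > spike_floor_pct)

    span = (
        int(round(epoch_span_ms[0] / 1000.0 * rec.fs_hz)),
        int(round(epoch_span_ms[1] / 1000.0 * rec.fs_hz)),
    )
    starts = np.round(beats.r_times_s * rec.fs_hz).astype(int) + span[0]
    width = span[1] - span[0] + 1

    epoch_mean = np.full((n_ch, n_beats), np.nan)
    for e, (s, ok) in enumerate(zip(starts, elig)):
        if not ok:
            continue
        sl = slice(max(s, 0), min(s + width, rec.n_samples))
        hit = bad_sample[:, sl].any(axis=1)
        keep[:, e] &= ~hit
        epoch_mean[:, e] = rec.ac[:, sl].mean(axis=1)

    # baseline-step rule: epoch mean level vs the robust spread across epochs.
    # The spread is floored at a fraction of the channel's own robust sample
    # SD so that the near-identical epoch means of a clean low-noise
    # recording are never self-flagged.
    n_spike_masked = int((~keep & np.tile(elig, (n_ch, 1))).sum())
    chan_sd = 1.4826 * mad[:, 0]
    for c in range(n_ch):
        em = epoch_mean[c]
        valid = np.isfinite(em)
        if valid.sum() < 3:
            continue
        m = np.median(em[valid])
        s = 1.4826 * np.median(np.abs(em[valid] - m))
        s = max(s, 0.05 * chan_sd[c])
        if s <= 0:
            continue
        keep[c, valid] &= np.abs(em[valid] - m) / s <= step_z

    unusable = [
        rec.channel_ids[c] for c in range(n_ch) if elig.any() and not keep[c].any()
    ]
    report = {
        "n_eligible": int(elig.sum()),
        "n_masked": int((np.tile(elig, (n_ch, 1)) & ~keep).sum()),
        "n_spike_masked": n_spike_masked,
        "unusable_channels": unusable,
    }
    return keep, report


def epoch_and_average(
    rec: OpticalRecording,
    beats: BeatSet,
    epoch_span_ms: tuple[float, float] = (0.0, 1000.0),
    keep_mask: np.ndarray | None = None,
    min_epochs: int = 100,
) -> list[PulseWaveform]:
    """Average R-wave-locked epochs per channel on a common post-R grid.

    Each kept epoch is resampled to the grid by evaluating a cubic spline of
    the channel's full time series at beat-time + grid offsets, then epochs
    are averaged.  Epochs truncated by the next beat or by the end of the
    recording are excluded.  Channels averaging fewer than ``min_epochs``
    epochs are flagged (``low_epochs``) but still returned.
    """
    if beats.n_beats == 0:
        raise ValueError("beat set is empty")
    if epoch_span_ms[1] < 600.0:
        raise ValueError("epoch span must cover at least 0-600 ms post R")
    grid_ms = epoch_grid(epoch_span_ms)
    elig = eligible_epochs(rec, beats, epoch_span_ms)
    if keep_mask is None:
        keep_mask = np.tile(elig, (rec.n_channels, 1))
    else:
        keep_mask = np.asarray(keep_mask, dtype=bool) & elig[None, :]

    t = rec.time_s
    waveforms = []
    for c in range(rec.n_channels):
        kept = beats.r_times_s[keep_mask[c]]
        if kept.size == 0:
            raise UnusableChannelError(
                f"channel {rec.channel_ids[c]} has no usable epochs"
            )
        spline = CubicSpline(t, rec.ac[c])
        sample_t = kept[:, None] + grid_ms[None, :] / 1000.0
        y = spline(sample_t).mean(axis=0)
        flags = {"low_epochs"} if kept.size < min_epochs else set()
        waveforms.append(
            PulseWaveform(
                time_ms=grid_ms,
                y=y,
                n_epochs=int(kept.size),
                unit_id=str(rec.channel_ids[c]),
                flags=flags,
            )
        )
    return waveforms


def baseline_waveform(
    w: PulseWaveform, window_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> PulseWaveform:
    """Zero the waveform on the first-peak-diastole window (128--256 ms).

    Subtracts the mean of ``y`` over the window, so the post-condition
    (window mean exactly zero) holds by construction and the operation is
    idempotent.
    """
    in_win = (w.time_ms >= window_ms[0]) & (w.time_ms <= window_ms[1])
    if not in_win.any():
        raise ValueError(f"waveform grid does not cover {window_ms} ms")
    y = w.y - w.y[in_win].mean()
    return PulseWaveform(
        time_ms=w.time_ms,
        y=y,
        n_epochs=w.n_epochs,
        unit_id=w.unit_id,
        baseline_window_ms=window_ms,
        flags=set(w.flags),
        annotations=dict(w.annotations),
    )


def save_waveforms(path, waveforms: list[PulseWaveform]) -> None:
    """Write averaged waveforms to HDF5 (waveforms/<unit>/{y,time_ms,n_epochs})."""
    with h5py.File(path, "w") as f:
        g = f.create_group("waveforms")
        for w in waveforms:
            u = g.create_group(w.unit_id)
            u.create_dataset("y", data=w.y, track_times=False)
            u.create_dataset("time_ms", data=w.time_ms, track_times=False)
            u.create_dataset("n_epochs", data=w.n_epochs, track_times=False)
            u.attrs["flags"] = ";".join(sorted(w.flags))


def load_waveforms(path) -> list[PulseWaveform]:
    out = []
    with h5py.File(path, "r") as f:
        for uid in sorted(f["waveforms"]):
            u = f["waveforms"][uid]
            flags = set(filter(None, u.attrs.get("flags", "").split(";")))
            out.append(
                PulseWaveform(
                    time_ms=u["time_ms"][()],
                    y=u["y"][()],
                    n_epochs=int(u["n_epochs"][()]),
                    unit_id=uid,
                    flags=flags,
                )
            )
    return out
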