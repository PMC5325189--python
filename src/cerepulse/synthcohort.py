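"""Seeded synthetic cohort generator with known ground truth.

Generates, per subject, a one-lead EKG trace (1000 Hz), a multichannel
optical AC-intensity recording (39.0625 Hz) with channel geometry, and a
covariate row -- all driven from a single integer seed so every downstream
estimator can be scored against the injected truth.

The cardiac pulse kernel rises smoothly to a systolic peak about 450 ms
after the R wave and then decays to a diastolic floor around 800 ms.  The
diastolic decay interpolates, as a function of a per-channel-group
``stiffness`` parameter in [0, 1], between a sustained concave fall-off
(compliant arteries, positive compliance index), a straight line
(stiffness 0.5, compliance 0), and a fast convex exponential drop (stiff
arteries, negative compliance).  The kernel is built on a 1 kHz internal
grid and lightly smoothed so it is twice differentiable; the smoothed
kernel is the ground truth the pipeline is expected to recover.

Cohort structure: ages drawn evenly across the decades of the configured
age range; arterial stiffness increases with age and decreases with the
physical-activity covariate at configurable slopes; frontoparietal channel
groups age faster than visual ones (regional scaling); pulse-pressure
amplitude grows slowly with age.  Default signal levels put the raw
single-beat pulse-to-noise ratio near 2:1 so that averaging >100 beats
yields a waveform SNR above 20:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .ekg import EkgTrace
from .optics import OpticalRecording
from .spatial import GEOMETRY_COLUMNS, with_derived
from .stats import compute_ecrf

KERNEL_FS_HZ = 1000.0
STIFFNESS_K_MAX = 7.0  # exponential curvature at the stiffness extremes

REGION_GROUPS = {
    "BA9": "frontoparietal",
    "BA7": "frontoparietal",
    "BA17": "visual",
    "BA18": "visual",
}


def region_group(label: str) -> str:
    return REGION_GROUPS.get(label, "other")


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror the resting-state protocol
    (360 s per montage at 39.0625 Hz optical / 1000 Hz EKG sampling)."""

    n_subjects: int = 47
    duration_s: float = 360.0
    fs_optical_hz: float = 39.0625
    fs_ekg_hz: float = 1000.0
    n_channels: int = 24
    age_range: tuple = (18, 77)
    mean_hr_bpm: float = 60.0
    hr_cv: float = 0.05
    ibi_bounds_s: tuple = (0.4, 2.0)
    # cohort effect sizes (stiffness units per normalized covariate in [-1, 1])
    age_stiffness_slope: float = 0.35
    fitness_stiffness_slope: float = 0.10
    stiffness_noise_sd: float = 0.05
    regional_age_scale: dict = field(
        default_factory=lambda: {"frontoparietal": 1.25, "other": 1.0, "visual": 0.25}
    )
    # signal levels (percent of mean channel intensity)
    pulse_pressure_base_pct: float = 1.0
    pulse_pressure_age_slope: float = 0.008  # % per year
    noise_sd_pct: float = 0.5
    drift_amplitude_pct: float = 1.0
    drift_freq_hz: float = 0.08
    # EKG morphology / noise
    ekg_noise_sd: float = 0.05
    ekg_wander_amp: float = 0.10
    n_ectopic_beats: int = 0
    # motion artifacts
    n_artifact_windows: int = 2
    artifact_duration_s: float = 2.0
    artifact_step_pct: float = 10.0
    artifact_spike_pct: float = 25.0
    include_out_of_range_channels: bool = True
    # pulse kernel timing (s post R wave)
    kernel_peak_s: float = 0.450
    kernel_end_s: float = 0.800
    kernel_rise_s: float = 0.180
    kernel_smooth_s: float = 0.041
    kernel_recovery_level: float = 0.06
    stiffness_k_max: float = STIFFNESS_K_MAX
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.fs_optical_hz <= 0 or self.fs_ekg_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        # default protocol must allow >100 averaged pulsations at 60 bpm
        if self.duration_s * self.mean_hr_bpm / 60.0 < 3:
            raise ValueError("recording too short for any epoch averaging")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls(**raw)
        if isinstance(cfg.age_range, list):
            cfg.age_range = tuple(cfg.age_range)
        return cfg


@dataclass
class GroundTruth:
    """Per-subject injected truth for scoring downstream estimators."""

    subject_id: str
    beat_times_s: np.ndarray
    stiffness: dict  # channel-group -> stiffness in [0, 1]
    pulse_pressure_pct: float
    noise_sd_pct: float
    artifact_windows_s: list = field(default_factory=list)
    ectopic_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    kernel_compliance: dict = field(default_factory=dict)  # group -> compliance
    kernel_peak_s: float = np.nan

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat_times_s must be strictly increasing")
        for g, s in self.stiffness.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"stiffness[{g}] = {s} outside [0, 1]")


@dataclass
class SubjectData:
    """One synthetic subject: recordings, geometry and truth."""

    ekg: EkgTrace
    optical: OpticalRecording
    geometry: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# pulse kernel


def diastolic_shape(u: np.ndarray, stiffness: float, k_max: float = STIFFNESS_K_MAX):
    """Normalized diastolic decay y(u), u in [0, 1], y(0)=1, y(1)=0.

    stiffness 0.5 gives the straight line 1-u; above 0.5 a convex exponential
    drop; below 0.5 the mirrored concave (sustained) fall-off.
    """
    u = np.asarray(u, dtype=float)
    k = k_max * abs(2.0 * stiffness - 1.0)
    if k < 1e-9:
        return 1.0 - u
    if stiffness > 0.5:  # stiff: fast convex decay
        return (np.exp(-k * u) - np.exp(-k)) / (1.0 - np.exp(-k))
    return 1.0 - (np.exp(k * u) - 1.0) / (np.exp(k) - 1.0)


def diastolic_shape_compliance(stiffness: float, k_max: float = STIFFNESS_K_MAX) -> float:
    """Closed-form compliance (area - 0.5) of the unsmoothed decay family."""
    k = k_max * abs(2.0 * stiffness - 1.0)
    if k < 1e-9:
        return 0.0
    g = 0.5 - 1.0 / k + 1.0 / (np.expm1(k))
    return -g if stiffness > 0.5 else g


def pulse_kernel(stiffness: float, config: SimConfig | None = None):
    """Noiseless single-beat kernel on a 1 kHz grid, peak normalized to 1.

    Piecewise: zero until the rise onset, half-cosine rise to the systolic
    peak, parametric diastolic decay to the trough, then a small
    end-diastolic recovery (half-cosine rise to a low plateau, tapering back
    to zero at the end of the beat) so the diastolic minimum is an isolated,
    well-conditioned trough rather than a flat tail; finally a short Hann
    smoothing pass so the kernel is smooth enough for spline resampling, and
    renormalization of the peak to 1.
    """
    cfg = config or SimConfig()
    n = int(round(1.0 * KERNEL_FS_HZ)) + 1
    t = np.arange(n) / KERNEL_FS_HZ
    y = np.zeros(n)
    t0 = cfg.kernel_peak_s - cfg.kernel_rise_s
    rise = (t >= t0) & (t < cfg.kernel_peak_s)
    y[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - t0) / cfg.kernel_rise_s))
    dia = (t >= cfg.kernel_peak_s) & (t <= cfg.kernel_end_s)
    u = (t[dia] - cfg.kernel_peak_s) / (cfg.kernel_end_s - cfg.kernel_peak_s)
    y[dia] = diastolic_shape(u, stiffness, cfg.stiffness_k_max)
    # end-diastolic recovery: trough -> low plateau -> taper to zero
    h = cfg.kernel_recovery_level
    r0, r1 = cfg.kernel_end_s, cfg.kernel_end_s + 0.080
    rise2 = (t > r0) & (t <= r1)
    y[rise2] = h * 0.5 * (1.0 - np.cos(np.pi * (t[rise2] - r0) / (r1 - r0)))
    plateau = (t > r1) & (t <= 0.950)
    y[plateau] = h
    taper = (t > 0.950) & (t <= 1.000)
    y[taper] = h * 0.5 * (1.0 + np.cos(np.pi * (t[taper] - 0.950) / 0.050))
    # smoothing: zero-phase Hann window convolution
    m = int(round(cfg.kernel_smooth_s * KERNEL_FS_HZ))
    m += 1 - m % 2  # odd length
    if m >= 3:
        win = np.hanning(m)
        win /= win.sum()
        y = np.convolve(y, win, mode="same")
    y /= y.max()
    return t, y


def kernel_ground_truth(t: np.ndarray, y: np.ndarray, cap_s: float = 0.9):
    """Compliance and peak time of a fine-grid kernel (generator-side truth).

    Mirrors the index definition on the dense grid: peak = argmax, diastolic
    reference = minimum between the peak and ``cap_s``, affine normalization,
    trapezoidal area minus 0.5.
    """
    i_peak = int(np.argmax(y))
    region = (t > t[i_peak]) & (t <= cap_s)
    idx = np.flatnonzero(region)
    i_dia = idx[int(np.argmin(y[region]))]
    seg_t = t[i_peak : i_dia + 1]
    seg_y = y[i_peak : i_dia + 1]
    tn = (seg_t - seg_t[0]) / (seg_t[-1] - seg_t[0])
    yn = (seg_y - seg_y[-1]) / (seg_y[0] - seg_y[-1])
    return float(np.trapezoid(yn, tn) - 0.5), float(t[i_peak])


# ---------------------------------------------------------------------------
# geometry


def make_geometry(
    n_channels: int = 24, include_out_of_range: bool = True
) -> pd.DataFrame:
    """Synthetic montage on the axial scalp plane, declared in Talairach mm.

    Channels are laid out in rows spanning the global box (X -45..45,
    Y -80..50): anterior rows labeled BA9/BA7 (frontoparietal), a middle
    unlabeled band, and a posterior row alternating BA17/BA18 (visual).
    Each channel is a 3 cm source-detector pair.  Optionally two pairs with
    out-of-bounds separations (1.5 and 7 cm) are appended to exercise the
    distance filter.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be at least 1")
    n_cols = 6
    row_y = [40.0, 15.0, -20.0, -60.0]
    row_label = ["BA9", "BA7", "other", "BA17"]
    rows = []
    for i in range(n_channels):
        r, c = divmod(i, n_cols)
        y = row_y[r % len(row_y)] - 30.0 * (r // len(row_y))
        x = -40.0 + 80.0 * (c / max(n_cols - 1, 1))
        label = row_label[r % len(row_label)]
        if label == "BA17" and c % 2 == 1:
            label = "BA18"
        rows.append(
            {
                "channel_id": f"ch{i:03d}",
                "src_x_mm": x - 15.0, "src_y_mm": y, "src_z_mm": 0.0,
                "det_x_mm": x + 15.0, "det_y_mm": y, "det_z_mm": 0.0,
                "region_label": label,
            }
        )
    if include_out_of_range:
        rows.append(
            {
                "channel_id": "chxs", "src_x_mm": -60.0, "src_y_mm": 0.0,
                "src_z_mm": 0.0, "det_x_mm": -45.0, "det_y_mm": 0.0,
                "det_z_mm": 0.0, "region_label": "other",
            }
        )
        rows.append(
            {
                "channel_id": "chxl", "src_x_mm": 60.0, "src_y_mm": -35.0,
                "src_z_mm": 0.0, "det_x_mm": 130.0, "det_y_mm": -35.0,
                "det_z_mm": 0.0, "region_label": "other",
            }
        )
    return with_derived(pd.DataFrame(rows, columns=GEOMETRY_COLUMNS))


# ---------------------------------------------------------------------------
# beat trains and EKG


def generate_beat_times(
    rng: np.random.Generator, config: SimConfig
) -> np.ndarray:
    """Beat train with lognormal interbeat jitter, clipped to the
    physiological plausibility band."""
    mean_ibi = 60.0 / config.mean_hr_bpm
    sigma = np.sqrt(np.log1p(config.hr_cv**2))
    t = 0.5 + rng.uniform(0.0, mean_ibi)
    times = []
    while t < config.duration_s - 0.2:
        times.append(t)
        ibi = mean_ibi * np.exp(rng.normal(-0.5 * sigma**2, sigma))
        t += float(np.clip(ibi, *config.ibi_bounds_s))
    return np.asarray(times)


def _qrs_template(tau: np.ndarray) -> np.ndarray:
    """QRS-like shape with the R peak exactly at tau = 0, plus a T bump."""
    r = np.exp(-0.5 * (tau / 0.012) ** 2)
    q = -0.15 * np.exp(-0.5 * ((tau + 0.028) / 0.010) ** 2)
    s = -0.20 * np.exp(-0.5 * ((tau - 0.032) / 0.012) ** 2)
    t_wave = 0.25 * np.exp(-0.5 * ((tau - 0.25) / 0.05) ** 2)
    return r + q + s + t_wave


def simulate_ekg(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> EkgTrace:
    """EKG voltage series with a QRS-like template at each truth beat time."""
    config.validate()
    if truth.beat_times_s.size and (
        truth.beat_times_s.min() < 0 or truth.beat_times_s.max() > config.duration_s
    ):
        raise ValueError("beat times outside the recording span")
    rng = rng or np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_ekg_hz))
    t = np.arange(n) / config.fs_ekg_hz
    v = np.zeros(n)
    half = int(0.45 * config.fs_ekg_hz)
    for bt, amp in [(b, 1.0) for b in truth.beat_times_s] + [
        (b, 0.7) for b in truth.ectopic_times_s
    ]:
        i0 = max(int(round(bt * config.fs_ekg_hz)) - half, 0)
        i1 = min(i0 + 2 * half, n)
        v[i0:i1] += amp * _qrs_template(t[i0:i1] - bt)
    if config.ekg_wander_amp > 0:
        v += config.ekg_wander_amp * np.sin(2 * np.pi * 0.22 * t + rng.uniform(0, 2 * np.pi))
        v += 0.5 * config.ekg_wander_amp * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    if config.ekg_noise_sd > 0:
        v += rng.normal(0.0, config.ekg_noise_sd, n)
    return EkgTrace(v=v, fs_hz=config.fs_ekg_hz, subject_id=truth.subject_id)


# ---------------------------------------------------------------------------
# optical recording


def simulate_optical(
    config: SimConfig,
    truth: GroundTruth,
    geometry: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> OpticalRecording:
    """Multichannel AC-intensity recording carrying the pulse kernel train.

    Each channel's group kernel is inserted at every beat time, scaled by the
    subject's pulse-pressure amplitude, riding on a per-channel DC level with
    slow drift, white noise, and boxcar-plus-spike motion artifacts inside
    the declared windows.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    geom = geometry if geometry is not None else make_geometry(
        config.n_channels, config.include_out_of_range_channels
    )
    groups = [region_group(lbl) for lbl in geom["region_label"]]
    n_ch = len(geom)
    n = int(round(config.duration_s * config.fs_optical_hz))
    t = np.arange(n) / config.fs_optical_hz

    trains = {}
    for g in sorted(set(groups)):
        kt, ky = pulse_kernel(truth.stiffness[g], config)
        train = np.zeros(n)
        for bt in truth.beat_times_s:
            i0 = int(np.ceil(bt * config.fs_optical_hz))
            i1 = min(int(np.floor((bt + kt[-1]) * config.fs_optical_hz)) + 1, n)
            if i0 >= n:
                continue
            train[i0:i1] += np.interp(t[i0:i1] - bt, kt, ky)
        trains[g] = train

    dc = rng.uniform(800.0, 1200.0, n_ch)
    pct = np.empty((n_ch, n))
    for c in range(n_ch):
        pct[c] = truth.pulse_pressure_pct * trains[groups[c]]
    if config.drift_amplitude_pct > 0:
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        pct += config.drift_amplitude_pct * np.sin(
            2 * np.pi * config.drift_freq_hz * t[None, :] + phases[:, None]
        )
    if truth.noise_sd_pct > 0:
        pct += rng.normal(0.0, truth.noise_sd_pct, (n_ch, n))
    for (w0, w1) in truth.artifact_windows_s:
        win = (t >= w0) & (t < w1)
        if not win.any():
            continue
        pct[:, win] += config.artifact_step_pct * rng.choice([-1.0, 1.0], size=(n_ch, 1))
        idx = np.flatnonzero(win)
        spikes = rng.choice(idx, size=min(5, idx.size), replace=False)
        pct[:, spikes] += config.artifact_spike_pct * rng.choice(
            [-1.0, 1.0], size=(n_ch, spikes.size)
        )
    ac = dc[:, None] * (1.0 + pct / 100.0)
    return OpticalRecording(
        ac=ac, fs_hz=config.fs_optical_hz, channel_ids=list(geom["channel_id"])
    )


# ---------------------------------------------------------------------------
# cohort


def _subject_truth(
    config: SimConfig,
    subject_id: str,
    base_stiffness: float,
    pulse_pressure_pct: float,
    rng: np.random.Generator,
) -> GroundTruth:
    beats = generate_beat_times(rng, config)
    ectopic = np.empty(0)
    if config.n_ectopic_beats > 0 and beats.size > 4:
        host = rng.choice(beats[1:-1], size=config.n_ectopic_beats, replace=False)
        ectopic = np.sort(host + 0.15)
    windows = []
    if config.n_artifact_windows > 0 and config.duration_s > 20:
        starts = np.sort(
            rng.uniform(5.0, config.duration_s - 5.0 - config.artifact_duration_s,
                        config.n_artifact_windows)
        )
        windows = [(float(s), float(s + config.artifact_duration_s)) for s in starts]
    stiffness = {}
    for g, scale in config.regional_age_scale.items():
        stiffness[g] = float(np.clip(0.5 + scale * (base_stiffness - 0.5), 0.0, 1.0))
    truth = GroundTruth(
        subject_id=subject_id,
        beat_times_s=beats,
        stiffness=stiffness,
        pulse_pressure_pct=pulse_pressure_pct,
        noise_sd_pct=config.noise_sd_pct,
        artifact_windows_s=windows,
        ectopic_times_s=ectopic,
    )
    for g, s in stiffness.items():
        kt, ky = pulse_kernel(s, config)
        comp, peak = kernel_ground_truth(kt, ky)
        truth.kernel_compliance[g] = comp
        truth.kernel_peak_s = peak
    return truth


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Cohort covariate table with ground-truth columns.

    Ages are spread evenly across the six decades of the age range; arterial
    stiffness rises with age and falls with the activity covariate; brain
    volumes shrink with age; OSPAN tracks frontoparietal compliance and WCST
    error counts track global stiffness, so the built-in effect directions
    mirror the hypothesized physiology.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2025]))
    lo, hi = config.age_range
    n_dec = 6
    edges = np.linspace(lo, hi, n_dec + 1)
    rows = []
    geom = make_geometry(config.n_channels, config.include_out_of_range_channels)
    for i in range(config.n_subjects):
        d = i % n_dec
        age = rng.uniform(edges[d], edges[d + 1])
        z_age = (age - (lo + hi) / 2.0) / ((hi - lo) / 2.0)
        gender = "M" if rng.integers(0, 2) else "F"
        activity = int(np.clip(round(2.0 + rng.normal(0, 1.1)), 0, 4))
        z_act = (activity - 2.0) / 2.0
        stiff = float(
            np.clip(
                0.5
                + config.age_stiffness_slope * z_age
                - config.fitness_stiffness_slope * z_act
                + rng.normal(0, config.stiffness_noise_sd),
                0.02, 0.98,
            )
        )
        pp = max(
            config.pulse_pressure_base_pct
            + config.pulse_pressure_age_slope * (age - (lo + hi) / 2.0)
            + rng.normal(0, 0.1),
            0.3,
        )
        bmi = 26.0 + 1.5 * z_age - 1.0 * z_act + rng.normal(0, 3.0)
        rhr = 66.0 - 5.0 * z_act + rng.normal(0, 6.0)
        sbp = 112.0 + 18.0 * z_age + rng.normal(0, 8.0)
        dbp = 72.0 + 4.0 * z_age + rng.normal(0, 5.0)
        etiv = rng.normal(1550.0, 130.0)
        rows.append(
            {
                "subject_id": f"sub{i:03d}",
                "age_years": round(float(age), 1),
                "gender": gender,
                "bmi": round(float(bmi), 1),
                "resting_hr_bpm": round(float(rhr), 1),
                "activity_level": activity,
                "systolic_mmhg": round(float(sbp), 1),
                "diastolic_mmhg": round(float(dbp), 1),
                "etiv_cm3": round(float(etiv), 1),
                "cortical_gray_cm3": round(
                    600.0 - 55.0 * z_age + 0.15 * (etiv - 1550.0) + rng.normal(0, 25.0), 1
                ),
                "cortical_white_cm3": round(
                    480.0 - 25.0 * z_age + 0.12 * (etiv - 1550.0) + rng.normal(0, 25.0), 1
                ),
                "subcortical_gray_cm3": round(
                    62.0 - 5.0 * z_age + 0.01 * (etiv - 1550.0) + rng.normal(0, 3.0), 1
                ),
                "true_stiffness": stiff,
                "true_pulse_pressure_pct": round(float(pp), 4),
            }
        )
    df = pd.DataFrame(rows)
    df["pulse_pressure_mmhg"] = df["systolic_mmhg"] - df["diastolic_mmhg"]
    df["ecrf_mets"] = compute_ecrf(df).round(3)

    # regional truth + cognition driven by regional stiffness
    scales = config.regional_age_scale
    for grp in ("frontoparietal", "visual"):
        s_grp = np.clip(0.5 + scales[grp] * (df["true_stiffness"] - 0.5), 0.0, 1.0)
        df[f"true_stiffness_{grp}"] = s_grp
        df[f"true_compliance_{grp}"] = [
            diastolic_shape_compliance(s) for s in s_grp
        ]
    df["true_compliance_global"] = [
        diastolic_shape_compliance(s) for s in df["true_stiffness"]
    ]
    cog_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2026]))
    df["ospan_score"] = np.clip(
        np.round(42.0 - 18.0 * df["true_stiffness_frontoparietal"]
                 + cog_rng.normal(0, 6.0, len(df))),
        0, 60,
    )
    df["wcst_total_trials"] = np.round(
        80.0 + 20.0 * df["true_stiffness"] + cog_rng.normal(0, 10.0, len(df))
    )
    df["wcst_errors"] = np.clip(
        np.round(12.0 + 14.0 * df["true_stiffness"] + cog_rng.normal(0, 5.0, len(df))),
        0, None,
    )
    df.attrs["geometry"] = geom
    return df


def iter_subjects(config: SimConfig, covariates: pd.DataFrame | None = None):
    """Yield (covariate row, SubjectData) pairs, generated lazily.

    Per-subject randomness is derived from independent seed-sequence spawns
    of the master seed, so the stream is reproducible and independent of how
    many subjects are consumed.
    """
    config.validate()
    cov = covariates if covariates is not None else simulate_covariates(config)
    geom = make_geometry(config.n_channels, config.include_out_of_range_channels)
    seeds = np.random.SeedSequence(config.seed).spawn(len(cov))
    for (_, row), ss in zip(cov.iterrows(), seeds):
        rng = np.random.default_rng(ss)
        truth = _subject_truth(
            config, row["subject_id"], row["true_stiffness"],
            row["true_pulse_pressure_pct"], rng,
        )
        ekg = simulate_ekg(config, truth, rng)
        optical = simulate_optical(config, truth, geom, rng)
        yield row, SubjectData(ekg=ekg, optical=optical, geometry=geom, truth=truth)


def simulate_cohort(config: SimConfig):
    """Covariate table plus the full list of per-subject recordings."""
    cov = simulate_covariates(config)
    subjects = [s for _, s in iter_subjects(config, cov)]
    return cov, subjects


# ---------------------------------------------------------------------------
# persistence


def save_subject(path, subject: SubjectData) -> None:
    """Write one subject to HDF5 (optical/ac, optical/time_s, ekg/v,
    ekg/time_s, truth/*); dataset timestamps are disabled so identical
    inputs produce byte-identical files."""
    tr = subject.truth
    with h5py.File(path, "w") as f:
        opt = f.create_group("optical")
        opt.create_dataset("ac", data=subject.optical.ac, track_times=False)
        opt.create_dataset("time_s", data=subject.optical.time_s, track_times=False)
        opt.attrs["fs_hz"] = subject.optical.fs_hz
        opt.create_dataset(
            "channel_ids",
            data=np.array(subject.optical.channel_ids, dtype="S16"),
            track_times=False,
        )
        ek = f.create_group("ekg")
        ek.create_dataset("v", data=subject.ekg.v, track_times=False)
        ek.create_dataset("time_s", data=subject.ekg.time_s, track_times=False)
        ek.attrs["fs_hz"] = subject.ekg.fs_hz
        g = f.create_group("truth")
        g.attrs["subject_id"] = tr.subject_id
        g.attrs["pulse_pressure_pct"] = tr.pulse_pressure_pct
        g.attrs["noise_sd_pct"] = tr.noise_sd_pct
        g.attrs["kernel_peak_s"] = tr.kernel_peak_s
        g.create_dataset("beat_times_s", data=tr.beat_times_s, track_times=False)
        g.create_dataset("ectopic_times_s", data=tr.ectopic_times_s, track_times=False)
        g.create_dataset(
            "artifact_windows_s",
            data=np.asarray(tr.artifact_windows_s, dtype=float).reshape(-1, 2),
            track_times=False,
        )
        names = sorted(tr.stiffness)
        g.create_dataset("group_names", data=np.array(names, dtype="S24"), track_times=False)
        g.create_dataset(
            "group_stiffness", data=np.array([tr.stiffness[k] for k in names]),
            track_times=False,
        )
        g.create_dataset(
            "group_compliance",
            data=np.array([tr.kernel_compliance[k] for k in names]),
            track_times=False,
        )


def load_subject(path, geometry: pd.DataFrame | None = None) -> SubjectData:
    with h5py.File(path, "r") as f:
        opt = f["optical"]
        optical = OpticalRecording(
            ac=opt["ac"][()],
            fs_hz=float(opt.attrs["fs_hz"]),
            channel_ids=[c.decode() for c in opt["channel_ids"][()]],
        )
        ek = f["ekg"]
        g = f["truth"]
        names = [c.decode() for c in g["group_names"][()]]
        truth = GroundTruth(
            subject_id=str(g.attrs["subject_id"]),
            beat_times_s=g["beat_times_s"][()],
            stiffness=dict(zip(names, g["group_stiffness"][()])),
            pulse_pressure_pct=float(g.attrs["pulse_pressure_pct"]),
            noise_sd_pct=float(g.attrs["noise_sd_pct"]),
            artifact_windows_s=[tuple(w) for w in g["artifact_windows_s"][()]],
            ectopic_times_s=g["ectopic_times_s"][()],
            kernel_compliance=dict(zip(names, g["group_compliance"][()])),
            kernel_peak_s=float(g.attrs["kernel_peak_s"]),
        )
        ekg = EkgTrace(
            v=ek["v"][()], fs_hz=float(ek.attrs["fs_hz"]), subject_id=truth.subject_id
        )
    return SubjectData(ekg=ekg, optical=optical, geometry=geometry, truth=truth)


def config_to_yaml(config: SimConfig, path) -> None:
    d = asdict(config)
    d["age_range"] = list(d["age_range"])
    d["ibi_bounds_s"] = list(d["ibi_bounds_s"])
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=True)
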