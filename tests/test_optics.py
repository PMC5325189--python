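"""Optical conditioning: normalization, band-pass, artifact masking, epoch
averaging and baselining, checked against the generator's injected truth."""

import numpy as np
import pytest

from cerepulse.ekg import BeatSet
from cerepulse.errors import UnusableChannelError
from cerepulse.optics import (
    OpticalRecording,
    PulseWaveform,
    bandpass_optical,
    baseline_waveform,
    eligible_epochs,
    epoch_and_average,
    epoch_grid,
    normalize_channels,
    reject_artifacts,
)
from cerepulse.synthcohort import SimConfig, iter_subjects, pulse_kernel
from tests.conftest import noiseless_config

FS = 39.0625


def rec_from(rows, fs=FS):
    return OpticalRecording(ac=np.atleast_2d(np.asarray(rows, float)), fs_hz=fs)


# ------------------------------------------------------------ normalization


def test_normalize_constant_channel_is_zero():
    rec, excluded = normalize_channels(rec_from(np.full(1000, 1000.0)))
    assert np.allclose(rec.ac, 0.0)
    assert excluded == []

def test_normalize_percent_units_and_gain_invariance():
    t = np.arange(2000) / FS
    base = 1.0 + 0.01 * np.sin(2 * np.pi * 1.2 * t)
    rec, _ = normalize_channels(rec_from([1000 * base, 5000 * base]))
    # 1 percent modulation => amplitude 1 in percent units
    assert np.max(rec.ac[0]) == pytest.approx(1.0, rel=1e-2)
    assert np.allclose(rec.ac[0], rec.ac[1], atol=1e-9)

def test_normalize_flags_nonpositive_channel():
    rec, excluded = normalize_channels(
        rec_from([np.full(100, 1000.0), np.full(100, -5.0)])
    )
    assert rec.n_channels == 1
    assert excluded == ["ch001"]


# ----------------------------------------------------------------- bandpass


def test_bandpass_two_tone_drift_vs_pulse():
    t = np.arange(int(120 * FS)) / FS
    drift = np.sin(2 * np.pi * 0.05 * t)
    pulse = 0.5 * np.sin(2 * np.pi * 1.2 * t)
    out = bandpass_optical(rec_from(drift + pulse))
    core = slice(int(10 * FS), -int(10 * FS))
    drift_out = bandpass_optical(rec_from(drift)).ac[0, core]
    pulse_out = bandpass_optical(rec_from(pulse)).ac[0, core]
    assert np.sqrt(np.mean(drift_out**2)) <= 0.1 * np.sqrt(np.mean(drift**2))
    assert np.sqrt(np.mean(pulse_out**2)) == pytest.approx(
        np.sqrt(np.mean(pulse**2)), rel=0.1
    )
    assert out.ac.shape == (1, t.size)

def test_bandpass_attenuates_10hz():
    t = np.arange(int(60 * FS)) / FS
    tone = np.sin(2 * np.pi * 10.0 * t)
    out = bandpass_optical(rec_from(tone)).ac[0, int(5 * FS) : -int(5 * FS)]
    assert np.sqrt(np.mean(out**2)) <= 0.2 * np.sqrt(0.5)

def test_bandpass_zero_in_zero_out():
    out = bandpass_optical(rec_from(np.zeros(4000)))
    assert np.allclose(out.ac, 0.0)

def test_bandpass_band_outside_nyquist_raises():
    with pytest.raises(ValueError):
        bandpass_optical(rec_from(np.zeros(4000)), 0.5, 25.0)


# ---------------------------------------------------------------- artifacts


def test_artifact_window_masks_exactly_overlapping_epochs():
    cfg = noiseless_config(n_artifact_windows=1, artifact_duration_s=3.0, seed=31)
    _, subj = next(iter_subjects(cfg))
    rec, _ = normalize_channels(subj.optical)
    beats = BeatSet(r_times_s=subj.truth.beat_times_s)
    keep, report = reject_artifacts(rec, beats)
    (w0, w1) = subj.truth.artifact_windows_s[0]
    elig = eligible_epochs(rec, beats)
    expected_masked = elig & (beats.r_times_s + 1.0 > w0) & (beats.r_times_s < w1)
    for c in range(rec.n_channels):
        masked = elig & ~keep[c]
        assert np.array_equal(masked, expected_masked)
    assert report["n_masked"] == expected_masked.sum() * rec.n_channels

def test_clean_recording_has_empty_mask(noiseless_subject):
    _, subj = noiseless_subject
    rec, _ = normalize_channels(subj.optical)
    beats = BeatSet(r_times_s=subj.truth.beat_times_s)
    keep, report = reject_artifacts(rec, beats)
    elig = eligible_epochs(rec, beats)
    assert report["n_masked"] == 0
    assert np.all(keep[:, elig])

def test_all_artifact_channel_reported_unusable(rng):
    n = int(60 * FS)
    quiet = rng.normal(0, 0.1, n)
    spiky = quiet.copy()
    spiky[:: int(FS)] += 50.0  # a large spike in every second
    rec = rec_from([quiet, spiky])
    beats = BeatSet(r_times_s=np.arange(1.0, 55.0, 1.05))
    keep, report = reject_artifacts(rec, beats)
    assert report["unusable_channels"] == ["ch001"]
    assert not keep[1].any()
    with pytest.raises(UnusableChannelError):
        epoch_and_average(rec, beats, keep_mask=keep, min_epochs=1)


# ----------------------------------------------------------------- epoching


def test_epoch_average_recovers_kernel_within_one_percent(noiseless_subject):
    _, subj = noiseless_subject
    rec, _ = normalize_channels(subj.optical)
    beats = BeatSet(r_times_s=subj.truth.beat_times_s)
    waveforms = epoch_and_average(rec, beats, min_epochs=10)
    w = baseline_waveform(waveforms[0])
    kt, ky = pulse_kernel(
        subj.truth.stiffness[_group_of(subj, w.unit_id)], _cfg(subj)
    )
    kernel_on_grid = subj.truth.pulse_pressure_pct * np.interp(
        w.time_ms / 1000.0, kt, ky
    )
    base_win = (w.time_ms >= 128) & (w.time_ms <= 256)
    kernel_on_grid = kernel_on_grid - kernel_on_grid[base_win].mean()
    # compare over the operative post-baseline range; the first ~130 ms of an
    # epoch legitimately contains the previous beat's end-diastolic tail
    core = (w.time_ms >= 128) & (w.time_ms <= 900)
    err = np.max(np.abs(w.y[core] - kernel_on_grid[core]))
    assert err <= 0.01 * kernel_on_grid.max()
    r = np.corrcoef(w.y[core], kernel_on_grid[core])[0, 1]
    assert r >= 0.999

def _group_of(subj, unit_id):
    from cerepulse.synthcohort import region_group

    label = subj.geometry.set_index("channel_id").loc[unit_id, "region_label"]
    return region_group(label)

def _cfg(subj):
    return SimConfig()  # kernel timing fields are defaults in the fixtures

def test_epoch_average_noise_attenuation(rng):
    sd = 1.0
    n = int(400 * FS)
    rec = rec_from(rng.normal(0, sd, n))
    beats = BeatSet(r_times_s=np.arange(1.0, 395.0, 1.05))
    w = epoch_and_average(rec, beats, min_epochs=100)[0]
    assert w.n_epochs >= 300
    rms = np.sqrt(np.mean(w.y**2))
    expected = sd / np.sqrt(w.n_epochs)
    assert rms <= 3 * expected
    assert expected / 2 <= rms <= 2 * expected

def test_truncated_epochs_are_excluded():
    n = int(30 * FS)
    rec = rec_from(np.zeros(n))
    beats = BeatSet(r_times_s=np.array([1.0, 1.5, 3.0, 4.5, 28.0, 29.9]))
    elig = eligible_epochs(rec, beats)
    # 1.0 truncated by 1.5; 29.9 truncated by end of recording; 28.0 ok
    assert list(elig) == [False, True, True, True, True, False]

def test_single_beat_gets_low_epoch_flag():
    rec = rec_from(np.zeros(int(10 * FS)))
    beats = BeatSet(r_times_s=np.array([2.0]))
    w = epoch_and_average(rec, beats, min_epochs=100)[0]
    assert w.n_epochs == 1
    assert "low_epochs" in w.flags

def test_epoch_span_must_cover_600ms():
    rec = rec_from(np.zeros(int(10 * FS)))
    with pytest.raises(ValueError):
        epoch_and_average(rec, BeatSet(r_times_s=np.array([2.0])), epoch_span_ms=(0, 500))


# ---------------------------------------------------------------- baseline


def test_baseline_window_mean_is_exactly_zero(rng):
    grid = epoch_grid()
    w = PulseWaveform(time_ms=grid, y=rng.normal(size=grid.size), n_epochs=100)
    b = baseline_waveform(w)
    win = (grid >= 128) & (grid <= 256)
    assert abs(b.y[win].mean()) < 1e-12 * max(1.0, np.abs(b.y).max())

def test_baseline_idempotent_and_constant_to_zero():
    grid = epoch_grid()
    b1 = baseline_waveform(PulseWaveform(time_ms=grid, y=np.sin(grid / 90.0), n_epochs=5))
    b2 = baseline_waveform(b1)
    assert np.allclose(b1.y, b2.y)
    const = baseline_waveform(PulseWaveform(time_ms=grid, y=np.full(grid.size, 7.0), n_epochs=5))
    assert np.allclose(const.y, 0.0)

def test_baseline_requires_window_coverage():
    w = PulseWaveform(time_ms=np.arange(300, 900, 25.6), y=np.zeros(24), n_epochs=5)
    with pytest.raises(ValueError):
        baseline_waveform(w)
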