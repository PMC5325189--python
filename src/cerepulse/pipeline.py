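"""End-to-end glue: recordings -> beats -> waveforms -> indices -> cohort table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ekg as ekg_mod
from .errors import EmptyRoiError
from . import optics, pulse, spatial
from .synthcohort import SimConfig, SubjectData, iter_subjects


@dataclass
class SubjectResult:
    """Per-subject pipeline output."""

    indices: pd.DataFrame  # per-channel indices merged with geometry/ROI info
    aggregates: dict  # e.g. {"compliance_global": ..., "amplitude_global": ...}
    beats: ekg_mod.BeatSet
    waveforms: list
    qc: dict = field(default_factory=dict)


def detect_beats(
    trace, z_threshold: float = 3.0, ibi_band_s=(0.4, 2.0)
) -> ekg_mod.BeatSet:
    """Band-pass (0.5-40 Hz) then threshold R-wave detection."""
    filtered = ekg_mod.bandpass_ekg(trace)
    return ekg_mod.detect_rwaves(filtered, z_threshold=z_threshold, ibi_band_s=ibi_band_s)


def default_rois() -> list[spatial.RoiSpec]:
    return [spatial.GLOBAL_ROI, spatial.FRONTOPARIETAL_ROI, spatial.VISUAL_ROI]


def process_subject(
    subject: SubjectData,
    bandpass: bool = True,
    artifact_rejection: bool = True,
    min_epochs: int = 100,
    epoch_span_ms: tuple[float, float] = (0.0, 1000.0),
    rois: list[spatial.RoiSpec] | None = None,
    beats: ekg_mod.BeatSet | None = None,
    split_half: bool = False,
) -> SubjectResult:
    """Run the full single-subject pipeline.

    Stages: R-wave detection on the EKG; source-detector distance filter on
    the geometry; percent-change normalization; artifact epoch masking (on
    the unfiltered series); optional 0.5-5 Hz band-pass; R-wave-locked epoch
    averaging on the native post-R grid; 128-256 ms baselining; per-channel
    amplitude and compliance; unweighted ROI means over QC-passing channels.

    ``split_half=True`` additionally computes block-1/block-2 indices from
    the first and second halves of the kept beats (for reliability checks).
    """
    if beats is None:
        beats = detect_beats(subject.ekg)
    geom, _ledger = spatial.filter_channels(subject.geometry)
    retained = set(geom["channel_id"])
    keep_rows = [i for i, c in enumerate(subject.optical.channel_ids) if c in retained]
    rec = subject.optical.copy_with(
        subject.optical.ac[keep_rows],
        channel_ids=[subject.optical.channel_ids[i] for i in keep_rows],
    )

    rec, excluded = optics.normalize_channels(rec)
    qc = {"channels_in": subject.optical.n_channels, "normalization_excluded": excluded}
    if artifact_rejection:
        keep_mask, report = optics.reject_artifacts(rec, beats, epoch_span_ms=epoch_span_ms)
        qc["artifacts"] = report
    else:
        keep_mask = None
    if bandpass:
        rec = optics.bandpass_optical(rec)

    waveforms = optics.epoch_and_average(
        rec, beats, epoch_span_ms=epoch_span_ms, keep_mask=keep_mask,
        min_epochs=min_epochs,
    )
    waveforms = [optics.baseline_waveform(w) for w in waveforms]
    indices = pulse.indices_per_unit(waveforms)
    indices = indices.merge(
        geom[["channel_id", "region_label", "talairach_x", "talairach_y", "sd_distance_cm"]],
        left_on="unit_id", right_on="channel_id", how="left",
    ).drop(columns="channel_id")

    aggregates = {}
    for roi in rois if rois is not None else default_rois():
        try:
            members = spatial.assign_units(geom, roi)
            for col, short in (("compliance", "compliance"), ("amplitude_pct", "amplitude")):
                aggregates[f"{short}_{roi.name}"] = pulse.aggregate_index(
                    indices, col, members=members
                )
        except EmptyRoiError:
            # the montage simply does not cover this regional ROI; the global
            # ROI must always resolve
            if roi.name == "global":
                raise
            qc.setdefault("empty_rois", []).append(roi.name)
            aggregates[f"compliance_{roi.name}"] = np.nan
            aggregates[f"amplitude_{roi.name}"] = np.nan

    if split_half:
        elig = optics.eligible_epochs(rec, beats, epoch_span_ms)
        mask = keep_mask if keep_mask is not None else np.tile(elig, (rec.n_channels, 1))
        usable = np.flatnonzero(mask.all(axis=0) & elig)
        halves = np.array_split(usable, 2)
        for bi, half in enumerate(halves, start=1):
            hm = np.zeros_like(mask)
            hm[:, half] = True
            ws = optics.epoch_and_average(
                rec, beats, epoch_span_ms=epoch_span_ms,
                keep_mask=hm & mask, min_epochs=1,
            )
            ws = [optics.baseline_waveform(w) for w in ws]
            half_idx = pulse.indices_per_unit(ws)
            g_members = spatial.assign_units(geom, spatial.GLOBAL_ROI)
            aggregates[f"compliance_global_block{bi}"] = pulse.aggregate_index(
                half_idx, "compliance", members=g_members
            )
            aggregates[f"amplitude_global_block{bi}"] = pulse.aggregate_index(
                half_idx, "amplitude_pct", members=g_members
            )

    return SubjectResult(
        indices=indices, aggregates=aggregates, beats=beats, waveforms=waveforms, qc=qc
    )


def run_cohort(
    config: SimConfig,
    bandpass: bool = True,
    artifact_rejection: bool = True,
    min_epochs: int = 100,
    split_half: bool = False,
) -> pd.DataFrame:
    """Generate and process a whole synthetic cohort.

    Subjects are generated lazily and processed one at a time; the returned
    covariate table gains ``est_*`` columns holding the estimated global and
    regional indices alongside the generator's ground-truth columns.
    """
    rows = []
    cov_rows = []
    for row, subject in iter_subjects(config):
        res = process_subject(
            subject,
            bandpass=bandpass,
            artifact_rejection=artifact_rejection,
            min_epochs=min_epochs,
            split_half=split_half,
        )
        est = {f"est_{k}": v for k, v in res.aggregates.items()}
        est["n_beats_detected"] = res.beats.n_beats
        rows.append(est)
        cov_rows.append(row)
    cov = pd.DataFrame(cov_rows).reset_index(drop=True)
    return pd.concat([cov, pd.DataFrame(rows)], axis=1)
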