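"""End-to-end feature extraction: synchronized per-instant feature tables.

The camera runs at 30 frames/s and the EEG at 128 samples/s; features are
assembled at the camera cadence.  Frame i (i >= 1) carries the four motion
features of the pair (i-1, i) and the EEG features of the 128-sample epoch
whose end time is nearest the frame's timestamp.  Frames earlier than the
first complete epoch (the first second of each trial) are dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import eeg as eegmod
from . import video as videomod
from .config import PipelineConfig
from .eeg import FREQ_FEATURE_NAMES, TIME_FEATURE_NAMES, BandSet, EEGStream
from .fusion import synchronize
from .synth import SessionConfig, Trial, iter_trials
from .video import IMAGE_FEATURE_NAMES, FrameSequence

logger = logging.getLogger(__name__)

ALL_FEATURE_NAMES = FREQ_FEATURE_NAMES + TIME_FEATURE_NAMES + IMAGE_FEATURE_NAMES


def extract_trial_features(eeg: EEGStream, frames: FrameSequence,
                           cfg: PipelineConfig | None = None,
                           bands: BandSet | None = None) -> pd.DataFrame:
    """Synchronized feature table for one trial (all 29 features).

    Rows are frame instants with a complete preceding epoch and a preceding
    frame; columns are the 12 frequency, 13 time and 4 image features plus
    ``time`` and bookkeeping columns copied from the streams.
    """
    cfg = cfg or PipelineConfig()
    bands = bands or BandSet()
    window = cfg.window
    if len(eeg) < window:
        raise ValueError("EEG stream shorter than one epoch")
    image = videomod.image_feature_table(frames, cfg.lk)
    frame_times = frames.times[1:]            # instant of the later frame

    end_indices = np.arange(window - 1, len(eeg))
    end_times = eeg.t0 + end_indices / eeg.rate
    idx, kept = synchronize(end_times, frame_times)
    epoch_ends = end_indices[idx[kept]]
    freq, time_feats, valid = eegmod.feature_matrix(eeg, epoch_ends,
                                                    bands=bands, window=window)
    if not valid.all():
        logger.warning("trial %s: %d degenerate epochs flagged and dropped",
                       eeg.trial_id, int((~valid).sum()))
    table = pd.DataFrame(
        np.hstack([freq, time_feats, image[kept]]),
        columns=list(ALL_FEATURE_NAMES),
    )
    table.insert(0, "time", frame_times[kept])
    table = table.loc[valid].reset_index(drop=True)
    if eeg.label is not None:
        table["label"] = eeg.label
    if eeg.trial_id is not None:
        table["trial_id"] = eeg.trial_id
    return table


def trial_table(trial: Trial, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature table for one synthetic trial with fold/subject bookkeeping."""
    table = extract_trial_features(trial.eeg, trial.frames, cfg)
    table["label"] = trial.label
    table["trial_id"] = trial.trial_id
    table["subject"] = trial.subject
    table["fold"] = trial.fold
    return table


def session_feature_table(session: SessionConfig,
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature table over a whole synthetic session (trials generated lazily
    so frame stacks never accumulate in memory)."""
    parts = [trial_table(trial, cfg) for trial in iter_trials(session)]
    return pd.concat(parts, ignore_index=True)
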