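"""Readers and writers: EEG CSV, frame directories, feature tables, models.

EEG CSV schemas (header required):

* ``timestamp_s,value`` -- already channel-averaged, one row per sample;
* ``timestamp_s,ch1..ch14`` -- per-electrode voltages, averaged on load.

Frames are a directory of ordered PNG/JPEG images (or a video container if
an imageio plugin can open it); color input is converted to grayscale with
ITU-R 601 luma weights.  Trained models are serialized to a versioned JSON
container; feature-name mismatch on load is a hard error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import SVMConfig
from .eeg import EEGStream
from .fusion import (CentroidScorer, DecisionModel, LDAProjection,
                     TrainedPipeline)
from .video import FrameSequence

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

_EEG_COLUMNS_AVG = ["timestamp_s", "value"]
_EEG_COLUMNS_RAW = ["timestamp_s"] + [f"ch{i}" for i in range(1, 15)]


def read_eeg_csv(path, rate: float = 128.0, tolerance: float = 0.01) -> EEGStream:
    """Load an EEG stream, averaging 14-channel input to one channel.

    Validates strictly increasing timestamps, absence of NaNs, and uniform
    sampling within ``tolerance`` (fraction) of the declared rate.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols == _EEG_COLUMNS_AVG:
        values = df["value"].to_numpy(float)
    elif cols == _EEG_COLUMNS_RAW:
        values = df[_EEG_COLUMNS_RAW[1:]].to_numpy(float).mean(axis=1)
    else:
        raise ValueError(
            f"{path.name}: expected columns {_EEG_COLUMNS_AVG} or "
            f"timestamp_s,ch1..ch14; got {cols}")
    ts = df["timestamp_s"].to_numpy(float)
    if np.isnan(values).any() or np.isnan(ts).any():
        row = int(np.flatnonzero(np.isnan(values) | np.isnan(ts))[0])
        raise ValueError(f"{path.name}: NaN at row {row}")
    dts = np.diff(ts)
    bad = np.flatnonzero(dts <= 0)
    if bad.size:
        raise ValueError(
            f"{path.name}: non-increasing timestamp at row {int(bad[0]) + 1}")
    if ts.size > 1:
        if np.abs(dts * rate - 1.0).max() > tolerance:
            row = int(np.argmax(np.abs(dts * rate - 1.0))) + 1
            raise ValueError(
                f"{path.name}: sampling not uniform at the declared "
                f"{rate:g} samples/s (row {row})")
    return EEGStream(samples=values, rate=rate, t0=float(ts[0]) if ts.size else 0.0,
                     trial_id=path.stem)


def write_eeg_csv(stream: EEGStream, path) -> None:
    df = pd.DataFrame({"timestamp_s": stream.times, "value": stream.samples})
    # default (repr) formatting: shortest exact representation, so a
    # write-then-read round trip is bit-exact
    df.to_csv(path, index=False)


_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
        img = np.clip(np.round(img), 0, 255)
    return img.astype(np.uint8)


def read_frames(path, rate: float = 30.0, t0: float = 0.0) -> FrameSequence:
    """Read a directory of ordered images (or a video file) as grayscale."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"{path}: no image files found")
        frames = [_to_gray(iio.imread(p)) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"{path}: inconsistent frame shapes {shapes}")
        stack = np.stack(frames)
    else:
        stack = np.stack([_to_gray(f) for f in iio.imiter(path)])
    return FrameSequence(frames=stack, rate=rate, t0=t0, trial_id=path.stem)


def write_frames(seq: FrameSequence, path) -> None:
    """Write one zero-padded PNG per frame into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frame)


def write_features_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sections_tsv(sections: pd.DataFrame, path) -> None:
    """Section table as BED-like TSV: start_s, end_s, label."""
    sections.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

def save_pipeline(pipe: TrainedPipeline, path) -> None:
    """Serialize a trained pipeline to versioned JSON."""
    data: dict = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(pipe.feature_names),
        "mode": pipe.mode,
        "scaler_mean": pipe.scaler_mean.tolist(),
        "scaler_std": pipe.scaler_std.tolist(),
        "k": pipe.k,
        "threshold": pipe.threshold,
    }
    if pipe.projection is not None:
        p = pipe.projection
        data["projection"] = {
            "vectors": p.vectors.tolist(),
            "eigenvalues": p.eigenvalues.tolist(),
            "global_mean": p.global_mean.tolist(),
            "class_means": {str(c): m.tolist() for c, m in p.class_means.items()},
            "priors": {str(c): q for c, q in p.priors.items()},
            "scatter_within": p.scatter_within.tolist(),
            "scatter_between": p.scatter_between.tolist(),
        }
    if pipe.model is not None:
        m = pipe.model
        data["svm"] = {
            "kernel": vars(m.config),
            "support_vectors": m.support_vectors.tolist(),
            "dual_coef": m.dual_coef.tolist(),
            "bias": m.bias,
        }
    if pipe.centroid is not None:
        data["centroid"] = {"c1": pipe.centroid.c1.tolist(),
                            "c2": pipe.centroid.c2.tolist()}
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_pipeline(path, expected_features=None) -> TrainedPipeline:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {data.get('format_version')}")
    names = tuple(data["feature_names"])
    if expected_features is not None and tuple(expected_features) != names:
        raise ValueError(
            f"feature-name mismatch: model was trained on {names}, "
            f"input provides {tuple(expected_features)}")
    projection = None
    if "projection" in data:
        p = data["projection"]
        projection = LDAProjection(
            vectors=np.array(p["vectors"]),
            eigenvalues=np.array(p["eigenvalues"]),
            k=data["k"],
            class_means={int(c): np.array(m) for c, m in p["class_means"].items()},
            global_mean=np.array(p["global_mean"]),
            priors={int(c): q for c, q in p["priors"].items()},
            scatter_within=np.array(p["scatter_within"]),
            scatter_between=np.array(p["scatter_between"]),
            feature_names=names,
        )
    model = None
    if "svm" in data:
        s = data["svm"]
        model = DecisionModel(
            config=SVMConfig(**s["kernel"]),
            support_vectors=np.array(s["support_vectors"]),
            dual_coef=np.array(s["dual_coef"]),
            bias=s["bias"],
            threshold=data["threshold"],
        )
    centroid = None
    if "centroid" in data:
        centroid = CentroidScorer(c1=np.array(data["centroid"]["c1"]),
                                  c2=np.array(data["centroid"]["c2"]))
    return TrainedPipeline(
        feature_names=names, mode=data["mode"],
        scaler_mean=np.array(data["scaler_mean"]),
        scaler_std=np.array(data["scaler_std"]),
        projection=projection, k=data["k"], model=model, centroid=centroid,
        threshold=data["threshold"],
    )
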