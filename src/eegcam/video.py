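"""Motion features from frontal-camera frame pairs.

Head movements of a user wearing a forward-facing camera translate the whole
scene in the image, so four cheap global features separate still from moving
frames: the mean absolute pixel difference of successive frames, the same
difference computed on Sobel edge-magnitude maps, and the average magnitude
and count of sparse optical-flow motion vectors (Shi-Tomasi corners tracked
with pyramidal Lucas-Kanade, i.e. the KLT scheme: for each corner the
displacement d minimizing the windowed squared residual
``E = sum_W (I_t(x - d) - I_{t+1}(x))^2`` between consecutive frames).

Differences are averaged over pixels (not summed) so values are independent
of the frame resolution.  Color input is reduced to grayscale (ITU-R 601
luma) on load; everything here operates on 8-bit grayscale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels as K

IMAGE_FEATURE_NAMES = ("pixel_diff", "edge_diff", "mv_avg_mag", "mv_count")


@dataclass
class FrameSequence:
    """Stack of same-shape grayscale frames at a uniform rate.

    ``frames`` is (n_frames, height, width) uint8; frame ``i`` is timestamped
    ``t0 + i / rate``.
    """

    frames: np.ndarray
    rate: float = 30.0
    t0: float = 0.0
    trial_id: str | None = None
    label: int | None = None
    #: optional generator metadata: true (x, y) crop offset per frame
    offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, height, width)")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit grayscale (uint8)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.frames)) / self.rate

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class LKParams:
    """Corner-detection and tracking parameters.

    Defaults: up to 400 Shi-Tomasi corners at quality 0.01 with 5 px minimum
    separation, tracked through a 21x21 window over 3 pyramid levels.
    ``min_mag`` is the acceptance threshold on motion-vector magnitude used
    by :func:`motion_features` (0 = count every tracked vector).
    """

    max_corners: int = 400
    quality: float = 0.01
    min_distance: float = 5.0
    window: int = 21
    levels: int = 3
    max_iter: int = 20
    eps: float = 0.01
    min_eig: float = 1e-4
    block_radius: int = 2
    min_mag: float = 0.0


@dataclass(frozen=True)
class MotionVector:
    """A tracked corner: origin (x, y) in the first frame, displacement
    (dx, dy) into the second, and its Euclidean magnitude in pixels."""

    origin: tuple[float, float]
    displacement: tuple[float, float]

    @property
    def magnitude(self) -> float:
        dx, dy = self.displacement
        return float(np.hypot(dx, dy))


def _as_float(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame)
    if f.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    return np.ascontiguousarray(f, dtype=np.float32)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"frame shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def pixel_difference(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Mean absolute intensity difference between two frames."""
    _check_pair(frame_a, frame_b)
    return float(K.mean_abs_diff(_as_float(frame_a), _as_float(frame_b)))


def sobel_magnitude(frame: np.ndarray) -> np.ndarray:
    """Per-pixel L2 magnitude of the horizontal and vertical 3x3 Sobel
    responses, replicate-padded at the borders."""
    f = _as_float(frame)
    if f.shape[0] < 3 or f.shape[1] < 3:
        raise ValueError("frame must be at least 3x3")
    return K.sobel_magnitude_map(f)


def edge_pixel_difference(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Mean absolute difference of the two frames' Sobel magnitude maps."""
    _check_pair(frame_a, frame_b)
    return float(K.mean_abs_diff(sobel_magnitude(frame_a),
                                 sobel_magnitude(frame_b)))


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 16:
            break
        pyr.append(K.pyr_down(pyr[-1]))
    return pyr


def _track_points(pyr_a: list[np.ndarray], pyr_b: list[np.ndarray],
                  pts: np.ndarray, params: LKParams) -> tuple[np.ndarray, np.ndarray]:
    """Pyramidal LK from coarse to fine; returns (displacements, status)."""
    n = pts.shape[0]
    half = params.window // 2
    disp = np.zeros((n, 2), np.float32)
    status = np.ones(n, np.uint8)
    nlev = min(len(pyr_a), len(pyr_b))
    for lev in range(nlev - 1, -1, -1):
        scale = np.float32(2.0 ** lev)
        lpts = np.ascontiguousarray(pts / scale)
        disp, st = K.lk_level(pyr_a[lev], pyr_b[lev], lpts, disp,
                              half, params.max_iter, params.eps, params.min_eig)
        status &= st
        if lev > 0:
            disp = disp * np.float32(2.0)
    return disp, status


def track_motion(frame_a: np.ndarray, frame_b: np.ndarray,
                 params: LKParams | None = None) -> list[MotionVector]:
    """Detect corners in ``frame_a`` and track them into ``frame_b``.

    Only successfully tracked points are returned; lost or degenerate points
    are dropped.  Featureless (e.g. uniform) frames yield an empty list.
    """
    _check_pair(frame_a, frame_b)
    params = params or LKParams()
    a = _as_float(frame_a)
    b = _as_float(frame_b)
    resp = K.corner_response(a, params.block_radius)
    border = max(params.window // 2 + 2, params.block_radius + 1)
    pts = K.select_corners(resp, params.max_corners, params.quality,
                           params.min_distance, border)
    if pts.shape[0] == 0:
        return []
    disp, status = _track_points(_pyramid(a, params.levels),
                                 _pyramid(b, params.levels), pts, params)
    return [
        MotionVector(origin=(float(pts[i, 0]), float(pts[i, 1])),
                     displacement=(float(disp[i, 0]), float(disp[i, 1])))
        for i in range(pts.shape[0]) if status[i]
    ]


def motion_features(vectors: Sequence[MotionVector],
                    min_mag: float = 0.0) -> tuple[float, int]:
    """(average magnitude, count) of vectors with magnitude >= ``min_mag``.

    The average is 0 when no vector passes the threshold.
    """
    mags = [v.magnitude for v in vectors if v.magnitude >= min_mag]
    if not mags:
        return 0.0, 0
    return float(np.mean(mags)), len(mags)


def image_feature_table(seq: FrameSequence,
                        params: LKParams | None = None) -> np.ndarray:
    """All four motion features for every consecutive frame pair.

    Row ``i`` describes the pair (frame i, frame i+1) and is assigned to the
    instant of frame ``i+1`` by the synchronizer; shape (n_frames - 1, 4)
    with columns ``pixel_diff, edge_diff, mv_avg_mag, mv_count``.

    This batched path (one compiled driver per trial) reuses each frame's
    pyramid and Sobel map across adjacent pairs but composes exactly the
    same kernels as the per-pair functions above.
    """
    params = params or LKParams()
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 frames")
    return K.image_features_stack(
        np.ascontiguousarray(seq.frames), params.max_corners, params.quality,
        params.min_distance, params.window, params.levels, params.max_iter,
        params.eps, params.min_eig, params.block_radius, params.min_mag,
    )
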