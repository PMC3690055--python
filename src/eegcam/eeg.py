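"""EEG stream handling and per-epoch feature extraction.

A headset EEG recording (channel-averaged, 128 samples/s) is scanned with a
128-sample sliding window (127-sample overlap by default).  Each window is
normalized -- DC level removed, then min-max scaled onto [-1, 1] -- and two
feature families are computed per epoch:

* 12 frequency-domain features: mean DFT magnitude inside fixed bands
  (3-15, 4-6, 5-7, 6-8, 7-9, 8-10, 9-11, 10-12, 15-30, 20-30, 51-64,
  59-61 Hz); at 128 samples / 128 Hz the DFT bins fall on integer Hz.
* 13 time-domain features: kurtosis, skewness, RMS amplitude (peak / sqrt(2)),
  zero-crossing count, minimum, maximum, variance and zero-crossing count of
  the first and second derivatives, and the Hjorth parameters activity,
  mobility and complexity.

Conventions are centralized here: raw (non-excess) standardized moments with
population variance, derivatives as first differences, and strict sign-change
zero crossings (exact zeros neither count nor break a crossing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default analysis window (samples) and hop (samples).
WINDOW = 128
STEP = 1

#: The fixed frequency bands, inclusive at both edges, in Hz.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (3, 15), (4, 6), (5, 7), (6, 8), (7, 9), (8, 10),
    (9, 11), (10, 12), (15, 30), (20, 30), (51, 64), (59, 61),
)

FREQ_FEATURE_NAMES = tuple(f"band_{lo:g}_{hi:g}" for lo, hi in DEFAULT_BANDS)
TIME_FEATURE_NAMES = (
    "kurtosis", "skewness", "rms_amplitude", "zero_crossings",
    "minimum", "maximum", "var_d1", "var_d2", "zc_d1", "zc_d2",
    "activity", "mobility", "complexity",
)


class DegenerateEpochError(ValueError):
    """Raised for constant (zero-variance) windows where normalization or
    moment-based statistics are undefined."""


@dataclass
class EEGStream:
    """Channel-averaged EEG samples at a uniform rate.

    Parameters
    ----------
    samples : array of voltage values (arbitrary units after averaging).
    rate : sampling rate in samples/s (128 for the headset device).
    t0 : timestamp of the first sample, seconds.
    trial_id : opaque identifier used for fold bookkeeping.
    label : optional trial class, 1 = no movement, 2 = movement.
    """

    samples: np.ndarray
    rate: float = 128.0
    t0: float = 0.0
    trial_id: str | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def times(self) -> np.ndarray:
        """Timestamp of each sample in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Epoch:
    """One normalized analysis window.

    ``end_index``/``end_time`` locate the window's last sample in the parent
    stream.  ``valid`` is False for degenerate (constant) windows, which are
    flagged rather than dropped so epoch counts are conserved.
    """

    values: np.ndarray
    end_index: int
    end_time: float
    valid: bool = True

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BandSet:
    """Ordered inclusive frequency intervals used for the spectral features."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}): low must be < high")
            if lo < 0:
                raise ValueError(f"band ({lo}, {hi}): negative frequency")

    def validate(self, rate: float) -> None:
        nyquist = rate / 2.0
        for lo, hi in self.bands:
            if hi > nyquist:
                raise ValueError(
                    f"band ({lo}, {hi}) exceeds the Nyquist frequency {nyquist} Hz"
                )

    def names(self) -> tuple[str, ...]:
        return tuple(f"band_{lo:g}_{hi:g}" for lo, hi in self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def normalize_epoch(raw: np.ndarray, end_index: int = WINDOW - 1,
                    end_time: float | None = None, rate: float = 128.0) -> Epoch:
    """Normalize a raw window: remove the DC level, then min-max scale to [-1, 1].

    The mean is subtracted first; the resulting [min, max] range is mapped
    affinely onto [-1, 1], so the output attains -1 and +1 exactly.

    Raises
    ------
    DegenerateEpochError
        If the window is constant (max == min), naming ``end_index``.
    """
    x = np.asarray(raw, dtype=np.float64)
    x = x - x.mean()
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateEpochError(
            f"constant EEG segment: epoch ending at sample {end_index} "
            "cannot be min-max normalized"
        )
    y = 2.0 * (x - lo) / (hi - lo) - 1.0
    if end_time is None:
        end_time = end_index / rate
    return Epoch(values=y, end_index=end_index, end_time=end_time)


def sliding_epochs(stream: EEGStream, window: int = WINDOW,
                   step: int = STEP) -> Iterator[Epoch]:
    """Yield normalized epochs over ``stream`` with the given window and hop.

    For step 1 this produces ``len(stream) - window + 1`` epochs (the default
    127-sample overlap).  Constant windows are yielded flagged invalid
    (``valid=False``) instead of being dropped, so downstream synchronization
    keeps a complete epoch grid.
    """
    n = len(stream)
    if n < window:
        logger.warning(
            "stream %s shorter than window (%d < %d): no epochs",
            stream.trial_id, n, window,
        )
        return
    x = stream.samples
    for end in range(window - 1, n, step):
        raw = x[end - window + 1 : end + 1]
        t = stream.t0 + end / stream.rate
        try:
            yield normalize_epoch(raw, end_index=end, end_time=t, rate=stream.rate)
        except DegenerateEpochError:
            yield Epoch(values=np.zeros(window), end_index=end, end_time=t,
                        valid=False)


def _band_bin_matrix(bands: BandSet, n: int, rate: float) -> np.ndarray:
    """(n_bands, n_bins) averaging matrix over inclusive DFT bins.

    At n = 128, rate = 128 the rfft bins sit on integer Hz, so a band
    (lo, hi) averages the magnitudes of bins lo..hi inclusive.
    """
    bands.validate(rate)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mat = np.zeros((len(bands), freqs.size))
    eps = 1e-9
    for i, (lo, hi) in enumerate(bands.bands):
        sel = (freqs >= lo - eps) & (freqs <= hi + eps)
        if not sel.any():  # pragma: no cover - bands always span >= 1 Hz
            raise ValueError(f"band ({lo}, {hi}) contains no DFT bin")
        mat[i, sel] = 1.0 / sel.sum()
    return mat


def frequency_features(epoch: Epoch | np.ndarray, bands: BandSet | None = None,
                       rate: float = 128.0) -> np.ndarray:
    """Mean DFT magnitude in each band (rectangular window, no taper)."""
    values = epoch.values if isinstance(epoch, Epoch) else np.asarray(epoch, float)
    bands = bands or BandSet()
    mag = np.abs(np.fft.rfft(values))
    return _band_bin_matrix(bands, values.size, rate) @ mag


def _zero_crossings(x: np.ndarray) -> int:
    """Strict sign-change count: adjacent sample product < 0."""
    return int(np.count_nonzero(x[:-1] * x[1:] < 0))


def time_features(epoch: Epoch | np.ndarray) -> dict[str, float]:
    """The 13 time-domain statistics of one epoch.

    Moments use population (biased) variance and raw standardized moments
    (normal kurtosis ~ 3).  ``rms_amplitude`` follows the pipeline's literal
    definition, peak absolute value divided by sqrt(2).  Derivatives are
    first differences.  Hjorth: activity = var(x),
    mobility = sqrt(var(d1)/var(x)), complexity = mobility(d1)/mobility(x).
    """
    x = epoch.values if isinstance(epoch, Epoch) else np.asarray(epoch, float)
    if x.size < 3:
        raise ValueError("time features need at least 3 samples")
    xc = x - x.mean()
    m2 = np.mean(xc ** 2)
    if m2 == 0.0:
        raise DegenerateEpochError("zero-variance epoch: moments undefined")
    m3 = np.mean(xc ** 3)
    m4 = np.mean(xc ** 4)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var_d1 = float(np.var(d1))
    var_d2 = float(np.var(d2))
    mobility = float(np.sqrt(var_d1 / m2))
    # complexity = mobility of d1 over mobility of x; 0/0 -> 0 for e.g. ramps
    mob_d1 = float(np.sqrt(var_d2 / var_d1)) if var_d1 > 0 else 0.0
    complexity = mob_d1 / mobility if mobility > 0 else 0.0
    return {
        "kurtosis": float(m4 / m2 ** 2),
        "skewness": float(m3 / m2 ** 1.5),
        "rms_amplitude": float(np.max(np.abs(x)) / np.sqrt(2.0)),
        "zero_crossings": _zero_crossings(x),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "var_d1": var_d1,
        "var_d2": var_d2,
        "zc_d1": _zero_crossings(d1),
        "zc_d2": _zero_crossings(d2),
        "activity": float(m2),
        "mobility": mobility,
        "complexity": complexity,
    }


# ---------------------------------------------------------------------------
# Vectorized batch path used by the pipeline (identical arithmetic to the
# per-epoch functions; cross-checked in the test suite).
# ---------------------------------------------------------------------------

def _normalize_rows(wins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise normalize; returns (normalized, valid mask)."""
    w = wins - wins.mean(axis=1, keepdims=True)
    lo = w.min(axis=1, keepdims=True)
    hi = w.max(axis=1, keepdims=True)
    rng = hi - lo
    valid = rng[:, 0] > 0
    rng[~valid, 0] = 1.0
    return 2.0 * (w - lo) / rng - 1.0, valid


def _zc_rows(x: np.ndarray) -> np.ndarray:
    return np.count_nonzero(x[:, :-1] * x[:, 1:] < 0, axis=1)


def feature_matrix(stream: EEGStream, end_indices: np.ndarray,
                   bands: BandSet | None = None,
                   window: int = WINDOW) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency and time features for the epochs ending at ``end_indices``.

    Returns ``(freq (m, 12), time (m, 13), valid (m,))``.  Invalid rows
    (constant windows) are zero-filled and flagged.
    """
    bands = bands or BandSet()
    ends = np.asarray(end_indices, dtype=np.intp)
    if ends.size == 0:
        return (np.zeros((0, len(bands))), np.zeros((0, 13)),
                np.zeros(0, dtype=bool))
    if ends.min() < window - 1 or ends.max() >= len(stream):
        raise ValueError("epoch end index out of range")
    all_wins = np.lib.stride_tricks.sliding_window_view(stream.samples, window)
    wins, valid = _normalize_rows(all_wins[ends - (window - 1)])

    mag = np.abs(np.fft.rfft(wins, axis=1))
    freq = mag @ _band_bin_matrix(bands, window, stream.rate).T

    xc = wins - wins.mean(axis=1, keepdims=True)
    m2 = np.mean(xc ** 2, axis=1)
    m2safe = np.where(m2 > 0, m2, 1.0)
    m3 = np.mean(xc ** 3, axis=1)
    m4 = np.mean(xc ** 4, axis=1)
    d1 = np.diff(wins, axis=1)
    d2 = np.diff(d1, axis=1)
    var_d1 = np.var(d1, axis=1)
    var_d2 = np.var(d2, axis=1)
    mobility = np.sqrt(var_d1 / m2safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        mob_d1 = np.where(var_d1 > 0, np.sqrt(var_d2 / np.where(var_d1 > 0, var_d1, 1.0)), 0.0)
        complexity = np.where(mobility > 0, mob_d1 / np.where(mobility > 0, mobility, 1.0), 0.0)
    time = np.column_stack([
        m4 / m2safe ** 2,
        m3 / m2safe ** 1.5,
        np.max(np.abs(wins), axis=1) / np.sqrt(2.0),
        _zc_rows(wins),
        wins.min(axis=1),
        wins.max(axis=1),
        var_d1,
        var_d2,
        _zc_rows(d1),
        _zc_rows(d2),
        m2,
        mobility,
        complexity,
    ])
    freq[~valid] = 0.0
    time[~valid] = 0.0
    return freq, time, valid
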