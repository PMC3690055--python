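"""Synthetic paired EEG + frontal-camera sessions with ground-truth labels.

The generator is phenomenological: it reproduces the class-conditional
structure the detector consumes, not the biophysics of electrode motion.

EEG.  Each trial is a sum of random-phase sinusoids grouped into a
low-frequency set (theta/alpha/low-beta, dominant when the head is still)
and a high-frequency set (upper beta plus a broadband 15-35 Hz component,
boosted by movement artifacts), a small mains component near 60 Hz, and
1/f-shaped background noise.  Movement trials (Class 2) scale the
high-frequency amplitudes up and the low-frequency amplitudes down.
Every component is amplitude-modulated by a slow log-OU envelope, and
subjects carry multiplicative lognormal gains on each component and on the
class-2 scaling factors, so the spectral contrast varies across epochs and
people the way single-channel headset recordings do.

Video.  A fixed per-subject noise texture is viewed through a crop window.
Still trials show only slow sub-pixel tremor (an AR(1) jitter with small
per-frame innovations); movement trials add a sinusoidal horizontal pan
emulating natural yaw, with a per-frame speed peaking at
``pan_peak_speed`` pixels.  Frames are rendered by bilinear resampling and
quantized to 8 bits.

Labels are per trial (a trial is either entirely still or entirely moving);
each synthetic subject contributes two trials per class, mirroring the
two-fold by-trial cross-validation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

from ._kernels import render_crops
from .eeg import EEGStream
from .video import FrameSequence


@dataclass(frozen=True)
class SessionConfig:
    """Study-condition parameters for one synthetic session."""

    duration_s: float = 47.0          # trial length, mid-range of 45-50 s
    n_subjects: int = 10
    trials_per_class: int = 2
    eeg_rate: float = 128.0
    frame_rate: float = 30.0
    frame_size: tuple[int, int] = (120, 160)   # (height, width) px
    seed: int = 0

    # EEG spectral mixture: (frequency Hz, amplitude) per component
    low_components: tuple[tuple[float, float], ...] = (
        (4.0, 1.0), (6.0, 1.2), (8.0, 1.5), (10.0, 1.2), (12.0, 0.8))
    high_components: tuple[tuple[float, float], ...] = (
        (18.0, 0.35), (22.0, 0.30), (26.0, 0.30), (29.0, 0.25))
    mains_component: tuple[float, float] = (60.0, 0.08)
    broadband_high: tuple[float, float, float] = (15.0, 35.0, 0.30)  # lo, hi, amp
    pink_level: float = 0.8
    class2_low_factor: float = 0.55
    class2_high_factor: float = 2.2

    # inter-subject / intra-trial variability (lognormal sigmas)
    subject_gain_sigma: float = 0.25
    subject_component_sigma: float = 0.30
    subject_factor_sigma: float = 0.35
    trial_sigma: float = 0.15
    envelope_tau_s: float = 2.0
    envelope_sigma: float = 0.30

    # camera motion
    pan_peak_speed: float = 4.0       # px per frame at pan peaks
    pan_freq_hz: float = 0.25         # natural yaw rate
    pan_pause_rate_hz: float = 0.08   # momentary holds during natural yaw
    pan_pause_dur_s: tuple[float, float] = (0.6, 1.2)
    jitter_step: float = 0.015         # AR(1) innovation, px per frame
    jitter_tau_s: float = 2.0
    adjust_rate_hz: float = 0.10      # rare small posture adjustments
    adjust_max_px: float = 6.0
    texture_smooth: float = 1.2       # texture correlation length, px

    def n_eeg_samples(self) -> int:
        return int(round(self.duration_s * self.eeg_rate))

    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def pan_amplitude(self) -> float:
        """Pan excursion (px) giving ``pan_peak_speed`` px/frame at peaks."""
        return self.pan_peak_speed * self.frame_rate / (2 * np.pi * self.pan_freq_hz)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject multiplicative variability, drawn once per subject."""

    gain: float
    component_jitter: tuple[float, ...]   # one per sinusoid component
    broadband_jitter: float
    low_factor: float                     # class-2 scaling, subject-specific
    high_factor: float
    texture_seed: int


@dataclass
class Trial:
    subject: int
    label: int                 # 1 = still, 2 = moving
    fold: int                  # 0 = first trial, 1 = second trial
    trial_id: str
    eeg: EEGStream
    frames: FrameSequence


def _subject_params(cfg: SessionConfig, rng: np.random.Generator) -> SubjectParams:
    ncomp = len(cfg.low_components) + len(cfg.high_components) + 1
    return SubjectParams(
        gain=float(np.exp(rng.normal(0.0, cfg.subject_gain_sigma))),
        component_jitter=tuple(
            np.exp(rng.normal(0.0, cfg.subject_component_sigma, ncomp))),
        broadband_jitter=float(np.exp(rng.normal(0.0, cfg.subject_component_sigma))),
        low_factor=float(cfg.class2_low_factor
                         * np.exp(rng.normal(0.0, cfg.subject_factor_sigma))),
        high_factor=float(cfg.class2_high_factor
                          * np.exp(rng.normal(0.0, cfg.subject_factor_sigma))),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _log_ou_envelope(n: int, rate: float, tau: float, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """exp(OU) amplitude envelope with unit median and correlation time tau."""
    rho = np.exp(-1.0 / (tau * rate))
    innov = rng.normal(0.0, sigma * np.sqrt(1 - rho ** 2), n)
    ou = np.empty(n)
    ou[0] = rng.normal(0.0, sigma)
    for i in range(1, n):
        ou[i] = rho * ou[i - 1] + innov[i]
    return np.exp(ou)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise, unit standard deviation."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f / f[1])
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _bandpass_noise(n: int, rate: float, lo: float, hi: float,
                    rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x / s if s > 0 else x


def generate_eeg(cfg: SessionConfig, label: int, seed: int | np.random.Generator,
                 subject: SubjectParams | None = None,
                 trial_id: str | None = None) -> EEGStream:
    """One trial of channel-averaged EEG for the given class.

    Class 2 multiplies high-frequency component amplitudes by the subject's
    ``high_factor`` and low-frequency amplitudes by ``low_factor``.
    """
    if label not in (1, 2):
        raise ValueError("label must be 1 or 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if subject is None:
        subject = _subject_params(cfg, rng)
    n = cfg.n_eeg_samples()
    t = np.arange(n) / cfg.eeg_rate

    comps = [(f, a, "low") for f, a in cfg.low_components]
    comps += [(f, a, "high") for f, a in cfg.high_components]
    comps.append((*cfg.mains_component, "mains"))

    # one slow amplitude envelope per band group: rhythms within a group
    # wax and wane together, so epoch-level spectral ratios fluctuate
    envs = {kind: _log_ou_envelope(n, cfg.eeg_rate, cfg.envelope_tau_s,
                                   cfg.envelope_sigma, rng)
            for kind in ("low", "high", "mains")}
    trial_jitter = {kind: np.exp(rng.normal(0.0, cfg.trial_sigma))
                    for kind in ("low", "high", "mains")}

    x = np.zeros(n)
    for i, (f, amp, kind) in enumerate(comps):
        a = amp * subject.component_jitter[i] * trial_jitter[kind]
        if label == 2:
            if kind == "high":
                a *= subject.high_factor
            elif kind == "low":
                a *= subject.low_factor
        phase = rng.uniform(0, 2 * np.pi)
        x += a * envs[kind] * np.sin(2 * np.pi * f * t + phase)

    lo, hi, bamp = cfg.broadband_high
    a = bamp * subject.broadband_jitter * trial_jitter["high"]
    if label == 2:
        a *= subject.high_factor
    x += a * envs["high"] * _bandpass_noise(n, cfg.eeg_rate, lo, hi, rng)

    x += cfg.pink_level * _pink_noise(n, rng)
    x *= subject.gain
    return EEGStream(samples=x, rate=cfg.eeg_rate, t0=0.0,
                     trial_id=trial_id, label=label)


def _make_texture(cfg: SessionConfig, seed: int) -> np.ndarray:
    """Trackable static scene: smoothed noise with margins for panning."""
    h, w = cfg.frame_size
    mx = int(np.ceil(cfg.pan_amplitude())) + 6
    my = 10
    rng = np.random.default_rng(seed)
    tex = rng.uniform(0.0, 1.0, (h + 2 * my + 2, w + 2 * mx + 2))
    tex = gaussian_filter(tex, cfg.texture_smooth)
    tex -= tex.min()
    tex /= tex.max()
    return (10.0 + 235.0 * tex).astype(np.float32)


def _micro_adjustments(cfg: SessionConfig, nf: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rare small posture adjustments: smooth few-pixel drifts to a new
    fixation point.  Present in both classes -- nobody holds a pose
    perfectly -- so still trials are not trivially static."""
    ax = np.zeros(nf)
    ay = np.zeros(nf)
    n_events = rng.poisson(cfg.adjust_rate_hz * nf / cfg.frame_rate)
    cx = cy = 0.0
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, nf - 10)))
        dur = int(rng.uniform(0.3, 0.8) * cfg.frame_rate)
        amp = rng.uniform(1.5, cfg.adjust_max_px)
        ang = rng.uniform(0, 2 * np.pi)
        dx, dy = amp * np.cos(ang), amp * np.sin(ang) * 0.3
        if abs(cx + dx) > cfg.adjust_max_px:
            dx = -dx
        if abs(cy + dy) > cfg.adjust_max_px:
            dy = -dy
        stop = min(nf, start + dur)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(stop - start) / max(1, dur)))
        ax[start:stop] += dx * ramp
        ay[start:stop] += dy * ramp
        if stop < nf:
            ax[stop:] += dx * ramp[-1] if stop > start else 0.0
            ay[stop:] += dy * ramp[-1] if stop > start else 0.0
        cx += dx
        cy += dy
    return ax, ay


def generate_frames(cfg: SessionConfig, label: int,
                    seed: int | np.random.Generator,
                    texture: np.ndarray | None = None,
                    trial_id: str | None = None) -> FrameSequence:
    """One trial of frames: static scene + tremor jitter (+ yaw pan for
    Class 2).  Raises if the pan excursion exceeds the texture margin."""
    if label not in (1, 2):
        raise ValueError("label must be 1 or 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if texture is None:
        texture = _make_texture(cfg, int(rng.integers(0, 2**31 - 1)))
    h, w = cfg.frame_size
    mx = (texture.shape[1] - 2 - w) // 2
    my = (texture.shape[0] - 2 - h) // 2
    nf = cfg.n_frames()
    t = np.arange(nf) / cfg.frame_rate

    rho = np.exp(-1.0 / (cfg.jitter_tau_s * cfg.frame_rate))
    jx = np.empty(nf)
    jy = np.empty(nf)
    ix = rng.normal(0.0, cfg.jitter_step, nf)
    iy = rng.normal(0.0, cfg.jitter_step, nf)
    jx[0] = jy[0] = 0.0
    for i in range(1, nf):
        jx[i] = rho * jx[i - 1] + ix[i]
        jy[i] = rho * jy[i - 1] + iy[i]

    xs = jx.copy()
    ys = jy.copy()
    ax, ay = _micro_adjustments(cfg, nf, rng)
    xs += ax
    ys += ay
    if label == 2:
        amp = cfg.pan_amplitude()
        if amp + 2 > mx:
            raise ValueError(
                f"pan amplitude {amp:.1f} px exceeds texture margin {mx} px")
        phase = rng.uniform(0, 2 * np.pi)
        # natural yaw: sinusoidal sweep with momentary holds, realized by
        # freezing the pan phase during pause intervals
        gate = np.ones(nf)
        n_pauses = rng.poisson(cfg.pan_pause_rate_hz * nf / cfg.frame_rate)
        edge = int(0.2 * cfg.frame_rate)
        for _ in range(n_pauses):
            start = int(rng.integers(0, nf))
            dur = int(rng.uniform(*cfg.pan_pause_dur_s) * cfg.frame_rate)
            stop = min(nf, start + dur)
            gate[start:stop] = 0.0
            a = max(0, start - edge)
            gate[a:start] = np.minimum(gate[a:start],
                                       np.linspace(1, 0, start - a, endpoint=False))
            b = min(nf, stop + edge)
            gate[stop:b] = np.minimum(gate[stop:b],
                                      np.linspace(0, 1, b - stop, endpoint=False))
        theta = phase + 2 * np.pi * cfg.pan_freq_hz * np.cumsum(gate) / cfg.frame_rate
        xs += amp * np.sin(theta)

    xs = np.clip(xs, -mx + 1.0, mx - 1.0)
    ys = np.clip(ys, -my + 1.0, my - 1.0)
    frames = render_crops(texture, xs.astype(np.float64), ys.astype(np.float64),
                          float(mx), float(my), h, w)
    return FrameSequence(frames=frames, rate=cfg.frame_rate, t0=0.0,
                         trial_id=trial_id, label=label,
                         offsets=np.column_stack([xs, ys]))


def iter_trials(cfg: SessionConfig) -> Iterator[Trial]:
    """Lazily generate all trials of a session (memory-friendly).

    For each subject: ``trials_per_class`` still trials then the same number
    of moving trials; the i-th trial of a class goes to fold i, matching the
    two-fold by-trial cross-validation split.  Determinism: every stream is
    a pure function of (config, seed).
    """
    root = np.random.SeedSequence(cfg.seed)
    subject_seqs = root.spawn(cfg.n_subjects)
    for s, sseq in enumerate(subject_seqs):
        child = sseq.spawn(1 + 2 * cfg.trials_per_class)
        subject = _subject_params(cfg, np.random.default_rng(child[0]))
        texture = _make_texture(cfg, subject.texture_seed)
        k = 1
        for label in (1, 2):
            for fold in range(cfg.trials_per_class):
                trial_id = f"s{s:02d}c{label}t{fold + 1}"
                rng = np.random.default_rng(child[k])
                k += 1
                eeg = generate_eeg(cfg, label, rng, subject, trial_id)
                frames = generate_frames(cfg, label, rng, texture, trial_id)
                yield Trial(subject=s, label=label, fold=fold,
                            trial_id=trial_id, eeg=eeg, frames=frames)


def manifest(cfg: SessionConfig) -> dict:
    """Session manifest: per-trial ids, classes and fold assignment."""
    trials = []
    for s in range(cfg.n_subjects):
        for label in (1, 2):
            for fold in range(cfg.trials_per_class):
                trials.append({
                    "trial_id": f"s{s:02d}c{label}t{fold + 1}",
                    "subject": s,
                    "label": label,
                    "fold": fold,
                })
    return {"config": asdict(cfg), "trials": trials}


def generate_session(cfg: SessionConfig) -> tuple[list[Trial], dict]:
    """Materialize all trials plus the manifest.

    Use :func:`iter_trials` for large sessions; a full default session holds
    ~1 GB of frames.
    """
    return list(iter_trials(cfg)), manifest(cfg)


def fixture_config(seed: int = 0, n_subjects: int = 1,
                   duration_s: float = 5.0) -> SessionConfig:
    """Miniature session configuration for unit tests and examples."""
    return SessionConfig(duration_s=duration_s, n_subjects=n_subjects, seed=seed)
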