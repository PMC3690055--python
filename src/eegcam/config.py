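"""Pipeline configuration: feature sets, SVM kernel grid, selection knobs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .eeg import FREQ_FEATURE_NAMES, TIME_FEATURE_NAMES
from .video import IMAGE_FEATURE_NAMES, LKParams

#: The feature-set combinations under comparison.  The six fused/EEG-only
#: combinations mirror the modality-comparison design; plain "image" is kept
#: so the camera modality can be scored on its own.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "freq": FREQ_FEATURE_NAMES,
    "time": TIME_FEATURE_NAMES,
    "freq+time": FREQ_FEATURE_NAMES + TIME_FEATURE_NAMES,
    "image": IMAGE_FEATURE_NAMES,
    "image+time": IMAGE_FEATURE_NAMES + TIME_FEATURE_NAMES,
    "image+freq": IMAGE_FEATURE_NAMES + FREQ_FEATURE_NAMES,
    "image+time+freq": (IMAGE_FEATURE_NAMES + TIME_FEATURE_NAMES
                        + FREQ_FEATURE_NAMES),
}


@dataclass(frozen=True)
class SVMConfig:
    """One kernel/parameter candidate: K per the four standard families.

    ``r`` is the kernel scale (gamma), ``c`` the additive constant (coef0),
    ``d`` the polynomial degree, ``cost`` the soft-margin C.
    """

    kernel: str = "rbf"            # linear | polynomial | rbf | sigmoid
    r: float = 1.0
    c: float = 0.0
    d: int = 3
    cost: float = 1.0

    def __post_init__(self):
        if self.kernel not in ("linear", "polynomial", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def default_svm_grid() -> tuple[SVMConfig, ...]:
    """Kernel candidates searched on the training fold: linear, RBF over a
    log-spaced scale range (including r = 8), small polynomial and sigmoid
    families, soft-margin cost in {1, 10}."""
    grid: list[SVMConfig] = []
    for cost in (1.0, 10.0):
        grid.append(SVMConfig(kernel="linear", cost=cost))
    for r in (0.125, 0.5, 2.0, 8.0, 32.0):
        for cost in (1.0, 10.0):
            grid.append(SVMConfig(kernel="rbf", r=r, cost=cost))
    for d in (2, 3):
        grid.append(SVMConfig(kernel="polynomial", r=1.0, c=1.0, d=d))
    for r in (0.01, 0.1):
        grid.append(SVMConfig(kernel="sigmoid", r=r, c=0.0))
    return tuple(grid)


def compact_svm_grid() -> tuple[SVMConfig, ...]:
    """Smaller linear+RBF grid used by the end-to-end benchmark."""
    grid: list[SVMConfig] = []
    for cost in (1.0, 10.0):
        grid.append(SVMConfig(kernel="linear", cost=cost))
    for r in (0.03125, 0.125, 0.5, 2.0, 8.0):
        for cost in (1.0, 10.0):
            grid.append(SVMConfig(kernel="rbf", r=r, cost=cost))
    return tuple(grid)


@dataclass
class PipelineConfig:
    """Everything the train/evaluate pipeline needs besides the data.

    Selection of the LDA dimension count, the kernel and the decision
    threshold all happen on an inner split of the training fold
    (``inner_frac`` train share, seed-fixed).  ``thin_train`` keeps every
    n-th frame instant per trial for model fitting (successive instants are
    highly redundant: the EEG windows overlap by 127/128 samples);
    evaluation always uses every instant.  ``svm_select_cap`` /
    ``svm_fit_cap`` bound the sample counts used for grid search and the
    final refit.
    """

    feature_set: str = "image+freq"
    window: int = 128
    step: int = 1
    lk: LKParams = field(default_factory=LKParams)
    candidate_ks: tuple[int, ...] = (1, 2, 3, 4, 6, 8, 12, 16)
    svm_grid: tuple[SVMConfig, ...] = field(default_factory=default_svm_grid)
    inner_frac: float = 0.7
    thin_train: int = 8
    svm_select_cap: int = 1200
    svm_fit_cap: int = 4000
    seed: int = 0

    def feature_names(self) -> tuple[str, ...]:
        try:
            return FEATURE_SETS[self.feature_set]
        except KeyError:
            raise ValueError(
                f"feature_set must be one of {sorted(FEATURE_SETS)}, "
                f"got {self.feature_set!r}") from None


def benchmark_pipeline_config(feature_set: str = "image+freq",
                              seed: int = 0) -> PipelineConfig:
    """Pipeline settings used for the synthetic end-to-end benchmark.

    Light corner/tracking settings: the synthetic scene moves globally, so
    few corners are needed; and a compact linear+RBF kernel grid.
    """
    return PipelineConfig(
        feature_set=feature_set,
        lk=LKParams(max_corners=40, window=11, levels=2, quality=0.03,
                    min_distance=7.0),
        svm_grid=compact_svm_grid(),
        candidate_ks=(1, 2, 4, 8, 16),
        seed=seed,
    )


def load_pipeline_config(path) -> PipelineConfig:
    """Read a PipelineConfig from YAML (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key == "lk":
            kwargs["lk"] = LKParams(**value)
        elif key == "svm_grid":
            kwargs["svm_grid"] = tuple(SVMConfig(**g) for g in value)
        elif key in ("candidate_ks",):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def dump_pipeline_config(cfg: PipelineConfig, path) -> None:
    data = asdict(cfg)
    data["svm_grid"] = [asdict(g) for g in cfg.svm_grid]
    data["candidate_ks"] = list(cfg.candidate_ks)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
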