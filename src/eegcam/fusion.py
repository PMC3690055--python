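"""Feature fusion, Fisher LDA, thresholded SVM, and evaluation.

The detector fuses per-instant EEG and camera features, reduces dimension
with Fisher's linear discriminant, and classifies with a soft-margin SVM
whose raw decision value is compared against a tuned threshold.  Class 1 is
"no head movement", Class 2 is "movement"; the SVM is trained with Class 1
as -1 and Class 2 as +1, so decision values above the threshold flag
movement.  Errors follow the screening convention: the Type-1 error is the
percentage of still instants flagged as moving, the Type-2 error the
percentage of moving instants missed, and the average error their mean.

Model selection (LDA dimension count, kernel family and parameters, decision
threshold) happens entirely on the training fold, via a seed-fixed inner
split; accuracy is reported with two-fold cross-validation where the folds
are whole trials (first trials vs second trials), never shuffled samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.svm import SVC

from .config import FEATURE_SETS, PipelineConfig, SVMConfig
from .eeg import EEGStream

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def synchronize(epoch_end_times: np.ndarray, frame_times: np.ndarray,
                eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Pair each frame instant with the nearest epoch end time.

    Returns ``(epoch_indices, kept)`` where ``kept`` marks frames not
    earlier than the first complete epoch (earlier frames are dropped with a
    logged count).  Ties between two equally near epochs go to the earlier
    epoch.
    """
    ends = np.asarray(epoch_end_times, dtype=float)
    ft = np.asarray(frame_times, dtype=float)
    if ends.size == 0 or ft.size == 0:
        raise ValueError("both streams must be non-empty")
    if ft.max() < ends.min() - eps or ft.min() > ends.max() + (ends[-1] - ends[0]):
        raise ValueError("EEG and frame time ranges do not overlap")
    kept = ft >= ends[0] - eps
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("synchronize: dropped %d frames before the first "
                    "complete epoch", n_dropped)
    pos = np.searchsorted(ends, ft)
    pos = np.clip(pos, 1, ends.size - 1)
    left = ends[pos - 1]
    right = ends[pos]
    idx = np.where(ft - left <= right - ft, pos - 1, pos)  # tie -> earlier
    idx[ft <= ends[0]] = 0
    return idx.astype(np.intp), kept


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAProjection:
    """Generalized eigenvectors of the Fisher criterion.

    ``vectors`` holds all projection directions as columns, sorted by
    non-increasing eigenvalue; with two classes only the leading direction
    is theoretically discriminative (between-class scatter has rank 1), the
    trailing ones are retained so the dimension count can be selected
    empirically.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    k: int
    class_means: dict[int, np.ndarray]
    global_mean: np.ndarray
    priors: dict[int, float]
    scatter_within: np.ndarray
    scatter_between: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def project(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        k = self.k if k is None else k
        return (np.asarray(X, float) - self.global_mean) @ self.vectors[:, :k]


def fit_lda(X: np.ndarray, y: np.ndarray,
            feature_names: Sequence[str] | None = None) -> LDAProjection:
    """Unregularized Fisher LDA: maximize |u' M_B u| / |u' M_W u|.

    M_W = sum_j q_j M_j (prior-weighted within-class covariances) and
    M_B = sum_j q_j (m_j - m)(m_j - m)', with empirical priors q_j.  Solved
    as the generalized symmetric eigenproblem (M_B, M_W); if M_W is
    singular a pseudo-inverse fallback is used (logged, not silent).
    Directions are oriented so the Class-2 mean projects non-negatively.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need samples from both classes")
    n, d = X.shape
    m = X.mean(axis=0)
    mw = np.zeros((d, d))
    mb = np.zeros((d, d))
    means: dict[int, np.ndarray] = {}
    priors: dict[int, float] = {}
    for cls in classes:
        Xc = X[y == cls]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        q = Xc.shape[0] / n
        mj = Xc.mean(axis=0)
        diff = Xc - mj
        mw += q * (diff.T @ diff) / Xc.shape[0]
        mb += q * np.outer(mj - m, mj - m)
        means[int(cls)] = mj
        priors[int(cls)] = q
    try:
        evals, evecs = scipy.linalg.eigh(mb, mw)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        logger.warning("fit_lda: singular within-class scatter, "
                       "falling back to pseudo-inverse")
        w, v = np.linalg.eig(np.linalg.pinv(mw) @ mb)
        evals, evecs = np.real(w), np.real(v)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evecs /= np.linalg.norm(evecs, axis=0, keepdims=True)
    if 1 in means and 2 in means:
        sign = np.sign((means[2] - means[1]) @ evecs)
        sign[sign == 0] = 1.0
        evecs = evecs * sign
    return LDAProjection(
        vectors=evecs, eigenvalues=evals, k=1, class_means=means,
        global_mean=m, priors=priors, scatter_within=mw, scatter_between=mb,
        feature_names=tuple(feature_names) if feature_names else None,
    )


def fisher_ratio(proj: LDAProjection, u: np.ndarray) -> float:
    """|u' M_B u| / |u' M_W u| for an arbitrary direction."""
    num = abs(u @ proj.scatter_between @ u)
    den = abs(u @ proj.scatter_within @ u)
    return float(num / den) if den > 0 else np.inf


# ---------------------------------------------------------------------------
# Centroid scorer (used for LDA-only classification and dimension selection)
# ---------------------------------------------------------------------------

@dataclass
class CentroidScorer:
    """Linear score in projected space: ||z - c1||^2 - ||z - c2||^2.

    Positive values point at Class 2.  This is the LDA-as-classifier rule
    once a threshold is tuned on it.
    """

    c1: np.ndarray
    c2: np.ndarray

    @classmethod
    def fit(cls, Z: np.ndarray, y: np.ndarray) -> "CentroidScorer":
        return cls(c1=Z[y == 1].mean(axis=0), c2=Z[y == 2].mean(axis=0))

    def scores(self, Z: np.ndarray) -> np.ndarray:
        d1 = ((Z - self.c1) ** 2).sum(axis=1)
        d2 = ((Z - self.c2) ** 2).sum(axis=1)
        return d1 - d2


def select_lda_dim(X: np.ndarray, y: np.ndarray,
                   candidate_ks: Sequence[int],
                   inner_frac: float = 0.7, seed: int = 0,
                   scorer_factory: Callable | None = None,
                   split: tuple[np.ndarray, np.ndarray] | None = None) -> int:
    """Pick the dimension count with the smallest held-out average error.

    For each candidate k the training part of a seed-fixed stratified inner
    split is projected to k dimensions, a simple classifier (centroid scorer
    with a threshold tuned on the training part) is fit, and the average
    error on the held-out part is recorded.  Ties break toward smaller k.
    """
    if len(candidate_ks) == 0:
        raise ValueError("candidate_ks must be non-empty")
    X = np.asarray(X, float)
    y = np.asarray(y)
    if split is None:
        tr, va = _stratified_split(y, inner_frac, seed)
    else:
        tr, va = split
    proj = fit_lda(X[tr], y[tr])
    max_k = proj.vectors.shape[1]
    best_k, best_err = None, np.inf
    factory = scorer_factory or CentroidScorer.fit
    for k in sorted(candidate_ks):
        if k < 1 or k > max_k:
            continue
        Ztr = proj.project(X[tr], k)
        Zva = proj.project(X[va], k)
        scorer = factory(Ztr, y[tr])
        thr = select_threshold(scorer.scores(Ztr), y[tr])
        err = error_rates(apply_threshold(scorer.scores(Zva), thr),
                          y[va]).average
        if err < best_err:
            best_k, best_err = k, err
    if best_k is None:
        raise ValueError("no candidate k is within 1..dimension count")
    return best_k


# ---------------------------------------------------------------------------
# SVM with explicit support set and tunable threshold
# ---------------------------------------------------------------------------

@dataclass
class DecisionModel:
    """A trained kernel classifier in explicit dual form.

    The raw decision value of an input x is the support-vector expansion
    ``sum_k a_k y_k K(x_k, x) + b`` (the quantity inside the sign function
    of the SVM decision rule), computed here directly from the stored
    support set; Class 2 is predicted when it exceeds ``threshold``.
    """

    config: SVMConfig
    support_vectors: np.ndarray       # (n_sv, k)
    dual_coef: np.ndarray             # a_k * y_k, signed
    bias: float
    threshold: float = 0.0

    def kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        sv = self.support_vectors
        c = self.config
        if c.kernel == "linear":
            return X @ sv.T
        if c.kernel == "polynomial":
            return (c.r * (X @ sv.T) + c.c) ** c.d
        if c.kernel == "rbf":
            d2 = ((X ** 2).sum(axis=1)[:, None] + (sv ** 2).sum(axis=1)[None, :]
                  - 2.0 * (X @ sv.T))
            return np.exp(-c.r * np.maximum(d2, 0.0))
        if c.kernel == "sigmoid":
            return np.tanh(c.r * (X @ sv.T) + c.c)
        raise ValueError(f"unknown kernel {c.kernel!r}")

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty(X.shape[0])
        step = 8192                      # bound the kernel-block footprint
        for i in range(0, X.shape[0], step):
            out[i:i + step] = (self.kernel_matrix(X[i:i + step])
                               @ self.dual_coef + self.bias)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return apply_threshold(self.decision_values(X), self.threshold)


def _svc_from_config(cfg: SVMConfig) -> SVC:
    kernel = {"linear": "linear", "polynomial": "poly", "rbf": "rbf",
              "sigmoid": "sigmoid"}[cfg.kernel]
    return SVC(kernel=kernel, C=cfg.cost, gamma=cfg.r if kernel != "linear" else "scale",
               coef0=cfg.c, degree=cfg.d)


def _fit_decision_model(X: np.ndarray, y: np.ndarray,
                        cfg: SVMConfig) -> DecisionModel:
    """Fit one SVM with labels mapped Class 1 -> -1, Class 2 -> +1."""
    ysvm = np.where(np.asarray(y) == 2, 1, -1)
    svc = _svc_from_config(cfg)
    svc.fit(np.asarray(X, float), ysvm)
    # sklearn orders classes_ ascending [-1, +1], so decision_function > 0
    # means +1 (Class 2) and dual_coef_ carries a_k * y_k directly.
    return DecisionModel(
        config=cfg,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
    )


def _stratified_split(y: np.ndarray, frac: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    tr_idx: list[np.ndarray] = []
    va_idx: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        cut = max(1, int(round(frac * idx.size)))
        cut = min(cut, idx.size - 1)
        tr_idx.append(idx[:cut])
        va_idx.append(idx[cut:])
    return np.sort(np.concatenate(tr_idx)), np.sort(np.concatenate(va_idx))


def _stratified_cap(y: np.ndarray, cap: int, seed: int) -> np.ndarray:
    """Indices of a class-balanced subsample of size <= cap."""
    if y.size <= cap:
        return np.arange(y.size)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        take = max(2, int(round(cap * idx.size / y.size)))
        keep.append(rng.choice(idx, size=min(take, idx.size), replace=False))
    return np.sort(np.concatenate(keep))


def train_svm(X: np.ndarray, y: np.ndarray,
              grid: Sequence[SVMConfig],
              inner_frac: float = 0.7, seed: int = 0,
              select_cap: int = 1200, fit_cap: int = 2500,
              split: tuple[np.ndarray, np.ndarray] | None = None) -> DecisionModel:
    """Grid-search the kernel family/parameters, refit the best, and return
    the model (threshold not yet tuned; see :func:`select_threshold`).

    Each candidate is fit on a capped, class-balanced subsample of the inner
    training part and scored by its threshold-tuned average error on the
    inner validation part; ties keep the earlier (simpler) grid entry.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need samples from both classes")
    if split is None:
        tr, va = _stratified_split(y, inner_frac, seed)
    else:
        tr, va = split
    sel = tr[_stratified_cap(y[tr], select_cap, seed + 1)]
    best: tuple[float, SVMConfig] | None = None
    for cfg in grid:
        model = _fit_decision_model(X[sel], y[sel], cfg)
        scores = model.decision_values(X[va])
        thr = select_threshold(scores, y[va])
        err = error_rates(apply_threshold(scores, thr), y[va]).average
        if best is None or err < best[0]:
            best = (err, cfg)
    fit_idx = tr[_stratified_cap(y[tr], fit_cap, seed + 2)]
    return _fit_decision_model(X[fit_idx], y[fit_idx], best[1])


def apply_threshold(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Class 2 iff the raw decision value strictly exceeds the threshold."""
    return np.where(np.asarray(scores) > threshold, 2, 1)


def select_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold minimizing the average of Type-1 and Type-2 errors.

    Candidates are the midpoints between consecutive unique decision values
    plus sentinels below/above the observed range; among minimizers the one
    nearest zero wins.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n2 = int((y == 2).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("tuning set must contain both classes")
    uniq = np.unique(scores)
    cand = np.concatenate([[uniq[0] - 1.0],
                           (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + 1.0]])
    # counts of scores <= t via sorted positions
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    is1_sorted = (y[order] == 1).astype(np.int64)
    cum1 = np.concatenate([[0], np.cumsum(is1_sorted)])
    pos = np.searchsorted(s_sorted, cand, side="right")
    below1 = cum1[pos]              # class-1 scores <= t  (correct rejections)
    below2 = pos - below1           # class-2 scores <= t  (misses)
    type1 = 100.0 * (n1 - below1) / n1
    type2 = 100.0 * below2 / n2
    avg = (type1 + type2) / 2.0
    best = avg.min()
    ties = np.flatnonzero(np.isclose(avg, best))
    return float(cand[ties[np.argmin(np.abs(cand[ties]))]])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorReport:
    """Type-1 / Type-2 / average error percentages with raw counts."""

    type1: float
    type2: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def average(self) -> float:
        return (self.type1 + self.type2) / 2.0

    def as_dict(self) -> dict:
        return {"type1": self.type1, "type2": self.type2,
                "average": self.average, "counts": dict(self.counts)}


def error_rates(predicted: np.ndarray, truth: np.ndarray) -> ErrorReport:
    """Type-1 error: % of Class-1 instants predicted Class 2; Type-2 error:
    % of Class-2 instants predicted Class 1; average: their mean."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    bad = set(np.unique(truth)) - {1, 2}
    if bad:
        raise ValueError(f"truth contains classes other than 1/2: {bad}")
    n1 = int((truth == 1).sum())
    n2 = int((truth == 2).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("a truth class is absent; its error is undefined")
    e1 = int(((truth == 1) & (predicted == 2)).sum())
    e2 = int(((truth == 2) & (predicted == 1)).sum())
    return ErrorReport(type1=100.0 * e1 / n1, type2=100.0 * e2 / n2,
                       counts={"n_class1": n1, "n_class2": n2,
                               "type1_errors": e1, "type2_errors": e2})


def roc_curve(scores: np.ndarray, truth: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over the unique decision values.

    Returns (FPR, TPR, area) with points ordered by increasing FPR and the
    area computed by the trapezoid rule (ties contribute half, matching the
    pairwise-comparison estimator).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    n1 = int((truth == 1).sum())
    n2 = int((truth == 2).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("ROC needs both classes")
    order = np.argsort(-scores, kind="stable")
    is2 = (truth[order] == 2).astype(float)
    # group tied scores so ties produce diagonal segments
    s_sorted = scores[order]
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    tp = np.concatenate([[0.0], np.add.reduceat(is2, np.concatenate([[0], boundaries])).cumsum()])
    fp = np.concatenate([[0.0], np.add.reduceat(1 - is2, np.concatenate([[0], boundaries])).cumsum()])
    fpr = fp / n1
    tpr = tp / n2
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


# ---------------------------------------------------------------------------
# Trained pipeline and two-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class TrainedPipeline:
    """Standardizer + LDA projection + decision rule for one feature set."""

    feature_names: tuple[str, ...]
    mode: str                         # lda_svm | lda_only | svm_only
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    projection: LDAProjection | None
    k: int
    model: DecisionModel | None       # None for lda_only
    centroid: CentroidScorer | None   # used by lda_only
    threshold: float

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"feature columns missing from input: {missing}")
        X = table.loc[:, list(self.feature_names)].to_numpy(float)
        return (X - self.scaler_mean) / self.scaler_std

    def decision_values(self, table: pd.DataFrame) -> np.ndarray:
        X = self._design(table)
        if self.projection is not None:
            X = self.projection.project(X, self.k)
        if self.mode == "lda_only":
            return self.centroid.scores(X)
        return self.model.decision_values(X)

    def classify(self, table: pd.DataFrame) -> np.ndarray:
        return apply_threshold(self.decision_values(table), self.threshold)


def _temporal_split_by_trial(trial_ids: np.ndarray, frac: float
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial temporal block split: the first ``frac`` of each trial's
    instants (in time order) train, the rest validate.

    Successive instants share 127 of 128 EEG samples, so a random sample
    split would put near-duplicates on both sides and make overfit models
    look good; block splitting keeps validation instants temporally
    disjoint from training ones.
    """
    tr: list[np.ndarray] = []
    va: list[np.ndarray] = []
    ids = pd.Series(trial_ids)
    for _, idx in ids.groupby(ids, sort=False).groups.items():
        idx = np.asarray(idx)
        cut = min(max(1, int(round(frac * idx.size))), idx.size - 1)
        tr.append(idx[:cut])
        va.append(idx[cut:])
    return np.sort(np.concatenate(tr)), np.sort(np.concatenate(va))


def _inner_split(thin: pd.DataFrame, y: np.ndarray, frac: float,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Inner train/validation split of a training fold for model selection.

    Preference order: hold out whole subjects (validation measures
    generalization to recordings the model never saw), else whole trials,
    else temporal blocks within the single available trial.  Trial- and
    subject-level holdout is what keeps selection honest here: validation
    instants from a seen trial share that trial's texture, pan realization
    and EEG envelopes, which flatters overfit models.
    """
    rng = np.random.default_rng(seed)

    def by_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        uniq = rng.permutation(np.unique(groups))
        if uniq.size < 3:
            return None
        n_va = max(1, int(round((1 - frac) * uniq.size)))
        va_groups = set(uniq[:n_va].tolist())
        va_mask = np.isin(groups, list(va_groups))
        tr_idx = np.flatnonzero(~va_mask)
        va_idx = np.flatnonzero(va_mask)
        for part in (tr_idx, va_idx):
            if part.size == 0 or np.unique(y[part]).size < 2:
                return None
        return tr_idx, va_idx

    if "subject" in thin.columns:
        split = by_groups(thin["subject"].to_numpy())
        if split is not None:
            return split
    if "trial_id" in thin.columns:
        split = by_groups(thin["trial_id"].to_numpy())
        if split is not None:
            return split
        tr, va = _temporal_split_by_trial(thin["trial_id"].to_numpy(), frac)
        if (np.unique(y[tr]).size == 2 and np.unique(y[va]).size == 2):
            return tr, va
    return _stratified_split(y, frac, seed)


def _select_k_and_kernel(Xs: np.ndarray, y: np.ndarray,
                         candidate_ks: Sequence[int],
                         grid: Sequence[SVMConfig],
                         tr: np.ndarray, va: np.ndarray,
                         select_cap: int, seed: int
                         ) -> tuple[int, SVMConfig]:
    """Joint dimension/kernel selection by validation average error.

    The projection is fit on the inner-training part only; every (k, kernel)
    pair is fit on a capped balanced subsample and scored with a tuned
    threshold on the inner-validation part.  Ties keep the smaller k and the
    earlier grid entry.
    """
    proj = fit_lda(Xs[tr], y[tr])
    max_k = proj.vectors.shape[1]
    sel = tr[_stratified_cap(y[tr], select_cap, seed + 1)]
    results: list[tuple[float, int, int, SVMConfig]] = []
    for k in sorted(set(candidate_ks)):
        if k < 1 or k > max_k:
            continue
        Zsel = proj.project(Xs[sel], k)
        Zva = proj.project(Xs[va], k)
        for gi, cfg in enumerate(grid):
            model = _fit_decision_model(Zsel, y[sel], cfg)
            scores = model.decision_values(Zva)
            thr = select_threshold(scores, y[va])
            err = error_rates(apply_threshold(scores, thr), y[va]).average
            results.append((err, k, gi, cfg))
    if not results:
        raise ValueError("no candidate k is within 1..dimension count")
    # parsimony margin: among near-ties prefer the smallest k and the
    # earliest (simplest) grid entry -- selection noise otherwise favors
    # needlessly complex models
    best_err = min(r[0] for r in results)
    margin = 0.2
    err, k, _, cfg = min((r for r in results if r[0] <= best_err + margin),
                         key=lambda r: (r[1], r[2]))
    return k, cfg


def _thin_by_trial(table: pd.DataFrame, stride: int) -> pd.DataFrame:
    if stride <= 1:
        return table
    keep = table.groupby("trial_id").cumcount() % stride == 0
    return table.loc[keep]


def fit_pipeline(train: pd.DataFrame, cfg: PipelineConfig,
                 mode: str = "lda_svm") -> TrainedPipeline:
    """Fit the full decision pipeline on one training fold.

    All selection (k, kernel, threshold) uses an inner split of the training
    fold only.  ``mode`` picks the classifier: ``lda_svm`` (projection then
    SVM), ``lda_only`` (projection then thresholded centroid score), or
    ``svm_only`` (SVM on standardized features).
    """
    if mode not in ("lda_svm", "lda_only", "svm_only"):
        raise ValueError(f"unknown mode {mode!r}")
    names = cfg.feature_names()
    thin = _thin_by_trial(train, cfg.thin_train).reset_index(drop=True)
    X = thin.loc[:, list(names)].to_numpy(float)
    y = thin["label"].to_numpy(int)
    if np.unique(y).size < 2:
        raise ValueError("training fold must contain both classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    projection = None
    k = 0
    centroid = None
    model = None
    tr, va = _inner_split(thin, y, cfg.inner_frac, cfg.seed)
    chosen_cfg = None
    if mode == "lda_svm":
        k, chosen_cfg = _select_k_and_kernel(
            Xs, y, cfg.candidate_ks, cfg.svm_grid, tr, va,
            cfg.svm_select_cap, cfg.seed)
        projection = fit_lda(Xs, y, feature_names=names)
        projection.k = k
        Z = projection.project(Xs, k)
    elif mode == "lda_only":
        k = select_lda_dim(Xs, y, cfg.candidate_ks, cfg.inner_frac, cfg.seed,
                           split=(tr, va))
        projection = fit_lda(Xs, y, feature_names=names)
        projection.k = k
        Z = projection.project(Xs, k)
    else:
        Z = Xs
        k = Z.shape[1]
    # the deployed model is fit on the inner-training part and its
    # threshold tuned on the held-out inner-validation part, so the
    # threshold never sees scores the model was fit on
    if mode == "lda_only":
        centroid = CentroidScorer.fit(Z[tr], y[tr])
        threshold = select_threshold(centroid.scores(Z[va]), y[va])
    elif mode == "lda_svm":
        fit_idx = tr[_stratified_cap(y[tr], cfg.svm_fit_cap, cfg.seed + 2)]
        model = _fit_decision_model(Z[fit_idx], y[fit_idx], chosen_cfg)
        threshold = select_threshold(model.decision_values(Z[va]), y[va])
        model.threshold = threshold
    else:
        model = train_svm(Z, y, cfg.svm_grid, cfg.inner_frac,
                          cfg.seed, cfg.svm_select_cap, cfg.svm_fit_cap,
                          split=(tr, va))
        threshold = select_threshold(model.decision_values(Z[va]), y[va])
        model.threshold = threshold
    logger.info("fit_pipeline[%s/%s]: k=%d kernel=%s threshold=%.4f",
                cfg.feature_set, mode, k,
                model.config if model else "centroid", threshold)
    return TrainedPipeline(
        feature_names=names, mode=mode, scaler_mean=mean, scaler_std=std,
        projection=projection, k=k, model=model, centroid=centroid,
        threshold=threshold,
    )


def twofold_cv(table: pd.DataFrame, cfg: PipelineConfig,
               mode: str = "lda_svm") -> dict:
    """Two-fold cross-validation with folds = whole trials.

    Fold 0 holds every subject's first trials, fold 1 the second trials;
    train on one, test on the other, swap, and average the error rates.
    """
    if "fold" not in table.columns:
        raise ValueError("table must carry a 'fold' column (by trial)")
    folds = sorted(table["fold"].unique())
    if len(folds) != 2:
        raise ValueError(f"expected exactly 2 folds, got {folds}")
    per_fold = []
    for train_fold, test_fold in ((folds[0], folds[1]), (folds[1], folds[0])):
        train = table[table["fold"] == train_fold]
        test = table[table["fold"] == test_fold]
        for part, name in ((train, "train"), (test, "test")):
            if part["label"].nunique() < 2:
                raise ValueError(f"{name} fold lacks a class")
        pipe = fit_pipeline(train, cfg, mode)
        report = error_rates(pipe.classify(test), test["label"].to_numpy(int))
        per_fold.append({
            "train_fold": int(train_fold),
            "k": pipe.k,
            "kernel": None if pipe.model is None else vars(pipe.model.config),
            "threshold": pipe.threshold,
            **report.as_dict(),
        })
    avg = {key: float(np.mean([f[key] for f in per_fold]))
           for key in ("type1", "type2", "average")}
    return {"mode": mode, "feature_set": cfg.feature_set,
            "per_fold": per_fold, "averaged": avg}


# ---------------------------------------------------------------------------
# Section rejection
# ---------------------------------------------------------------------------

def reject_sections(labels: np.ndarray, frame_times: np.ndarray,
                    eeg: EEGStream) -> tuple[list[EEGStream], pd.DataFrame]:
    """Excise the EEG intervals labeled as movement.

    Each frame's label governs the half-open interval [frame time, next
    frame time); the last interval extends by the median frame spacing.
    Consecutive same-label intervals merge into sections.  Returns the
    retained EEG segments (Class-1 sections intersected with the stream,
    plus any stream portion outside the governed span) and the section
    table with columns start_s, end_s, label.
    """
    labels = np.asarray(labels)
    ft = np.asarray(frame_times, float)
    if labels.size != ft.size:
        raise ValueError("labels and frame_times must align")
    dt = float(np.median(np.diff(ft))) if ft.size > 1 else 1.0
    edges = np.concatenate([ft, [ft[-1] + dt]])
    rows = []
    start = edges[0]
    cur = labels[0]
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != cur:
            rows.append((start, edges[i], int(cur)))
            if i < labels.size:
                start = edges[i]
                cur = labels[i]
    sections = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])

    t = eeg.times
    t_end = eeg.t0 + len(eeg) / eeg.rate
    keep = np.zeros(len(eeg), dtype=bool)
    keep |= (t < edges[0]) | (t >= edges[-1])       # ungoverned EEG retained
    for start_s, end_s, label in rows:
        if label == 1:
            keep |= (t >= start_s) & (t < end_s)
    segments: list[EEGStream] = []
    if keep.any():
        idx = np.flatnonzero(keep)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(starts, stops):
            lo, hi = idx[a], idx[b]
            segments.append(EEGStream(
                samples=eeg.samples[lo:hi + 1], rate=eeg.rate,
                t0=eeg.t0 + lo / eeg.rate, trial_id=eeg.trial_id,
                label=eeg.label,
            ))
    return segments, sections
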