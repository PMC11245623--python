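"""ICP-similarity features, regularized LDA, and tournament evaluation.

The classifier never sees raw coordinates: each pip is represented by its
vector of ICP registration MSEs against every training pip.  The training
similarity matrix holds entry [i, j] = ICP(pip i → pip j).mse with a zero
diagonal; a test matrix holds test-vs-train MSEs.  Columns are z-scored with
parameters fitted on the training matrix only.  A linear discriminant
analysis on these features learns the within- and between-variety structure
of the similarities, and repeated random train subsampling ("tournament"
sessions) accumulates an accuracy estimate over many splits.

Because the feature dimension equals the number of training pips, the
within-class scatter is singular; the LDA is therefore ridge-regularized
(S_w + γ·mean(diag(S_w))·I) with a small default γ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .icp_registration import icp
from .synthetic_seeds import PointCloud

__all__ = [
    "SimilarityFeatures",
    "LdaModel",
    "TournamentResult",
    "build_train_matrix",
    "build_test_matrix",
    "all_pairs_mse",
    "fit_normalizer",
    "apply_normalizer",
    "lda_fit",
    "lda_predict",
    "run_session",
    "tournament",
]


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------


def build_train_matrix(clouds: Sequence[PointCloud], **icp_kwargs) -> np.ndarray:
    """All-pairs ICP-MSE matrix; entry [i, j] registers cloud i onto cloud j.

    The diagonal is zero by construction (self-alignment) without running
    ICP.  The matrix is directional and deliberately not symmetrized.
    """
    n = len(clouds)
    if n < 2:
        raise ValueError("need at least 2 clouds")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                M[i, j] = icp(clouds[i], clouds[j], **icp_kwargs).mse
    return M


def build_test_matrix(
    test_clouds: Sequence[PointCloud],
    train_clouds: Sequence[PointCloud],
    **icp_kwargs,
) -> np.ndarray:
    """Test-vs-train ICP-MSE matrix, shape (n_test, n_train)."""
    if len(test_clouds) == 0 or len(train_clouds) == 0:
        raise ValueError("both cloud sets must be non-empty")
    M = np.zeros((len(test_clouds), len(train_clouds)))
    for k, tc in enumerate(test_clouds):
        for j, trc in enumerate(train_clouds):
            M[k, j] = icp(tc, trc, **icp_kwargs).mse
    return M


def all_pairs_mse(clouds: Sequence[PointCloud], **icp_kwargs) -> np.ndarray:
    """Directional ICP-MSE over a pooled cloud list, cached for tournaments."""
    return build_train_matrix(clouds, **icp_kwargs)


@dataclass(frozen=True)
class SimilarityFeatures:
    """Normalized train/test feature matrices plus the fitted parameters."""

    train_matrix: np.ndarray
    test_matrix: np.ndarray
    column_means: np.ndarray
    column_stds: np.ndarray

    @classmethod
    def from_raw(cls, train_raw: np.ndarray, test_raw: np.ndarray) -> "SimilarityFeatures":
        means, stds = fit_normalizer(train_raw)
        return cls(
            train_matrix=apply_normalizer(train_raw, (means, stds)),
            test_matrix=apply_normalizer(test_raw, (means, stds)),
            column_means=means,
            column_stds=stds,
        )


def fit_normalizer(train_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and standard deviation of the training matrix."""
    M = np.asarray(train_matrix, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    return M.mean(axis=0), M.std(axis=0)


def apply_normalizer(
    matrix: np.ndarray, params: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Z-score columns with train-fitted parameters; zero-variance → zeros."""
    means, stds = params
    M = np.asarray(matrix, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (M - means) / stds
    return np.where(stds > 0, out, 0.0)


# ---------------------------------------------------------------------------
# linear discriminant analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LdaModel:
    """Discriminant projection with nearest-centroid decision rule."""

    scalings: np.ndarray  # (n_features, n_components), n_components <= C-1
    centroids: np.ndarray  # (C, n_components)
    class_labels: np.ndarray
    gamma: float


def lda_fit(features: np.ndarray, labels: Sequence, gamma: float = 1e-3) -> LdaModel:
    """Fit regularized LDA by the generalized scatter eigenproblem.

    Solves S_b v = λ (S_w + γ·mean(diag(S_w))·I) v and keeps the top C−1
    eigendirections; class centroids are the projected class means.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    p = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.zeros((classes.size, p))
    for c in range(classes.size):
        Xc = X[y_idx == c]
        mu = Xc.mean(axis=0)
        means[c] = mu
        centered = Xc - mu
        Sw += centered.T @ centered
        diff = (mu - grand)[:, None]
        Sb += counts[c] * (diff @ diff.T)
    ridge = gamma * max(float(np.mean(np.diag(Sw))), 1e-12)
    Sw_reg = Sw + ridge * np.eye(p)
    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1][: classes.size - 1]
    scalings = eigvecs[:, order]
    return LdaModel(
        scalings=scalings,
        centroids=means @ scalings,
        class_labels=classes,
        gamma=gamma,
    )


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Nearest class centroid in discriminant space (ties → first label)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.scalings.shape[0]:
        raise ValueError("feature width does not match the fitted model")
    proj = X @ model.scalings
    d2 = ((proj[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return model.class_labels[np.argmin(d2, axis=1)]


# ---------------------------------------------------------------------------
# tournament evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TournamentResult:
    per_session_accuracy: tuple[float, ...]
    accumulative_accuracy: float
    confusion: pd.DataFrame  # rows: true class, cols: predicted, counts
    n_sessions: int


def _stratified_subsample(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    idx: list[np.ndarray] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        k = max(2, int(round(fraction * members.size)))
        k = min(k, members.size)
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def run_session(
    train_raw: np.ndarray,
    train_labels: np.ndarray,
    test_raw: np.ndarray,
    test_labels: np.ndarray,
    gamma: float = 1e-3,
) -> tuple[float, pd.DataFrame, np.ndarray]:
    """One classification session from raw (unnormalized) MSE matrices."""
    feats = SimilarityFeatures.from_raw(train_raw, test_raw)
    model = lda_fit(feats.train_matrix, train_labels, gamma=gamma)
    pred = lda_predict(model, feats.test_matrix)
    acc = float(np.mean(pred == np.asarray(test_labels)))
    classes = np.unique(np.concatenate([np.asarray(train_labels), np.asarray(test_labels)]))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t_lab, p_lab in zip(test_labels, pred):
        conf.loc[t_lab, p_lab] += 1
    return acc, conf, pred


def tournament(
    train_pool: Sequence[PointCloud],
    train_labels: Sequence,
    test_pool: Sequence[PointCloud],
    test_labels: Sequence,
    n_sessions: int = 100,
    rng_seed: int = 0,
    train_fraction: float = 0.8,
    gamma: float = 1e-3,
    cache: tuple[np.ndarray, np.ndarray] | None = None,
    use_cache: bool = True,
    **icp_kwargs,
) -> TournamentResult:
    """Repeated train-subsample / classify sessions with accumulated accuracy.

    Each session draws a stratified random subsample of the training pool
    (``train_fraction`` per class), builds the train and test similarity
    matrices for that subsample, normalizes, fits the LDA and classifies the
    full test pool.  The all-pairs ICP table over the pools is computed once
    and indexed per session (pass ``cache=(train_train, test_train)`` to
    reuse a precomputed one); session results are identical whether entries
    are cached or recomputed per session.
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    if len(train_pool) == 0 or len(test_pool) == 0:
        raise ValueError("pools must be non-empty")
    if np.unique(train_labels).size < 2:
        raise ValueError("training pool needs at least 2 classes")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if use_cache:
        if cache is None:
            tt = build_train_matrix(train_pool, **icp_kwargs)
            st = build_test_matrix(test_pool, train_pool, **icp_kwargs)
        else:
            tt, st = cache
    rng = np.random.default_rng(rng_seed)
    accs: list[float] = []
    confusion: pd.DataFrame | None = None
    total_correct = 0
    total_classified = 0
    for _ in range(n_sessions):
        sel = _stratified_subsample(train_labels, train_fraction, rng)
        if use_cache:
            train_raw = tt[np.ix_(sel, sel)]
            test_raw = st[:, sel]
        else:
            subset = [train_pool[i] for i in sel]
            train_raw = build_train_matrix(subset, **icp_kwargs)
            test_raw = build_test_matrix(test_pool, subset, **icp_kwargs)
        acc, conf, _ = run_session(
            train_raw, train_labels[sel], test_raw, test_labels, gamma=gamma
        )
        accs.append(acc)
        total_correct += int(round(acc * len(test_pool)))
        total_classified += len(test_pool)
        confusion = conf if confusion is None else confusion.add(conf, fill_value=0)
    assert confusion is not None
    return TournamentResult(
        per_session_accuracy=tuple(accs),
        accumulative_accuracy=total_correct / total_classified,
        confusion=confusion.astype(int),
        n_sessions=n_sessions,
    )
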