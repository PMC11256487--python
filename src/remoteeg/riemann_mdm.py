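"""Single-epoch classification in the Riemannian geometry of SPD matrices.

Each epoch is summarized by an ERP "super-trial" covariance: the class
prototype waveform (the mean training oddball response) is stacked on top
of the epoch, and the sample covariance of the stacked signal is shrunk
toward a scaled identity.  The cross-covariance blocks between prototype
and epoch encode how much of the stereotyped response the epoch contains,
which is what separates oddball from standard trials.

Covariances live on the manifold of symmetric positive-definite (SPD)
matrices with the affine-invariant metric

    d(A, B) = sqrt(sum_i log^2 lambda_i),   lambda_i = eigenvalues of A^-1 B.

Class centers are Karcher (Frechet) means under this metric, computed by
fixed-point iteration on the tangent-space average; a Euclidean
(arithmetic-mean) fallback is provided for ablation.  The minimum-distance-
to-means (MDM) rule assigns an epoch to the class with the nearest center,
and stratified k-fold cross-validation reports pooled accuracy, a
rank-based AUC over the distance-difference score, and a Pearson chi-square
test (no continuity correction) on the 2x2 confusion table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .erp_stats import EpochSet
from .errors import ConvergenceError

__all__ = [
    "MdmModel",
    "ClassifierReport",
    "erp_super_trial_covariance",
    "riemannian_distance",
    "euclidean_distance",
    "geometric_mean",
    "fit_mdm",
    "predict_and_score",
    "evaluate_cv",
    "chi_square_confusion",
    "rank_auc",
    "is_spd",
]

SYMMETRY_TOL = 1e-10


def is_spd(a: np.ndarray, tol: float = SYMMETRY_TOL) -> bool:
    """True when *a* is symmetric (to *tol*) with positive eigenvalues."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        return False
    if np.max(np.abs(a - a.T)) > tol * max(1.0, np.max(np.abs(a))):
        return False
    try:
        linalg.cholesky(a, lower=True)
    except linalg.LinAlgError:
        return False
    return True


def _require_spd(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not is_spd(a):
        raise ValueError(f"{name} is not symmetric positive-definite")
    return a


def erp_super_trial_covariance(
    epoch: np.ndarray, prototype: np.ndarray, shrinkage: float = 0.1
) -> np.ndarray:
    """Prototype-augmented covariance of one epoch, shrunk to be SPD.

    The prototype (channels x time) is stacked over the epoch, giving a
    2C x T super-trial whose sample covariance is shrunk toward
    ``scale * I`` with ``scale`` = the average variance:

        C_out = (1 - shrinkage) * cov + shrinkage * scale * I

    With ``shrinkage=0`` the raw covariance is returned only when it can be
    full rank (T - 1 >= 2C); otherwise a rank-deficiency error instructs
    the caller to use shrinkage > 0.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    prototype = np.atleast_2d(np.asarray(prototype, dtype=float))
    if epoch.shape != prototype.shape:
        raise ValueError(
            f"epoch shape {epoch.shape} != prototype shape {prototype.shape}"
        )
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")
    z = np.vstack([prototype, epoch])
    d, t = z.shape
    if shrinkage == 0.0 and t - 1 < d:
        raise ValueError(
            f"covariance of a {d}-row super-trial from {t} samples is rank "
            f"deficient; use shrinkage > 0"
        )
    cov = np.cov(z)
    scale = float(np.trace(cov)) / d
    if scale <= 0:
        raise ValueError("super-trial has zero variance; covariance undefined")
    out = (1.0 - shrinkage) * cov + shrinkage * scale * np.eye(d)
    return 0.5 * (out + out.T)


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant distance between two SPD matrices.

    ``sqrt(sum log^2 lambda_i)`` over the eigenvalues of ``A^-1 B``,
    computed via the symmetric generalized eigenproblem ``B v = lambda A v``.
    """
    a = _require_spd(a, "A")
    b = _require_spd(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    lam = linalg.eigh(b, a, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Frobenius distance, the flat-metric fallback."""
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b), ord="fro"))


def _sqrtm_spd(a: np.ndarray):
    w, v = linalg.eigh(a)
    w = np.clip(w, 1e-300, None)
    sq = (v * np.sqrt(w)) @ v.T
    inv_sq = (v / np.sqrt(w)) @ v.T
    return sq, inv_sq


def _logm_spd(a: np.ndarray) -> np.ndarray:
    w, v = linalg.eigh(a)
    return (v * np.log(np.clip(w, 1e-300, None))) @ v.T


def _expm_sym(a: np.ndarray) -> np.ndarray:
    w, v = linalg.eigh(a)
    return (v * np.exp(w)) @ v.T


def geometric_mean(
    matrices: Sequence[np.ndarray], tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Karcher/Frechet mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration: map all matrices to the tangent space at the
    current estimate M, average, and map back:

        M <- M^1/2 exp( mean_i log(M^-1/2 A_i M^-1/2) ) M^1/2

    terminating when the Frobenius norm of the tangent average drops below
    *tol*.  For commuting matrices this is the elementwise geometric mean;
    the mean is equivariant under congruence ``A -> G' A G``.
    """
    mats = [_require_spd(m, f"matrices[{i}]") for i, m in enumerate(matrices)]
    if not mats:
        raise ValueError("need at least one matrix")
    d = mats[0].shape[0]
    for i, m in enumerate(mats):
        if m.shape != (d, d):
            raise ValueError(f"matrices[{i}] has shape {m.shape}, expected {(d, d)}")
    if len(mats) == 1:
        return mats[0].copy()
    mean = np.mean(mats, axis=0)  # arithmetic init
    norm = np.inf
    for _ in range(max_iter):
        sq, inv_sq = _sqrtm_spd(mean)
        tangent = np.mean([_logm_spd(inv_sq @ m @ inv_sq) for m in mats], axis=0)
        tangent = 0.5 * (tangent + tangent.T)
        norm = float(np.linalg.norm(tangent, ord="fro"))
        if norm < tol:
            return 0.5 * (mean + mean.T)
        mean = sq @ _expm_sym(tangent) @ sq
    raise ConvergenceError(
        f"geometric mean did not converge in {max_iter} iterations "
        f"(final tangent norm {norm:.3e} > tol {tol:.1e})",
        final_norm=norm,
    )


@dataclass
class MdmModel:
    """Fitted minimum-distance-to-means classifier."""

    classes: tuple[str, ...]  # sorted lexicographically
    means: dict[str, np.ndarray]  # class -> SPD center
    prototype: np.ndarray  # (channels, times) oddball ERP prototype
    metric: str = "riemannian"  # riemannian | euclidean
    shrinkage: float = 0.1
    positive_class: str = "oddball"

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        if self.metric == "riemannian":
            return riemannian_distance(a, b)
        return euclidean_distance(a, b)

    @property
    def dim(self) -> int:
        return next(iter(self.means.values())).shape[0]


def _covariances(epochs: EpochSet, prototype: np.ndarray, shrinkage: float) -> np.ndarray:
    return np.stack(
        [erp_super_trial_covariance(e, prototype, shrinkage) for e in epochs.epochs]
    )


def fit_mdm(
    epochs: EpochSet,
    labels: Sequence[str] | None = None,
    metric: str = "riemannian",
    shrinkage: float = 0.1,
    positive_class: str = "oddball",
) -> MdmModel:
    """Fit class centers from labeled training epochs.

    The ERP prototype is the mean of the training epochs of the positive
    (oddball) class; each epoch's super-trial covariance is then averaged
    per class with the Karcher mean (or arithmetically for the Euclidean
    metric).
    """
    if metric not in ("riemannian", "euclidean"):
        raise ValueError(f"metric must be 'riemannian' or 'euclidean', got {metric!r}")
    y = np.asarray(labels if labels is not None else epochs.labels)
    if y.shape[0] != epochs.n_epochs:
        raise ValueError(f"{y.shape[0]} labels for {epochs.n_epochs} epochs")
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 epochs per class, got {counts}")
    if positive_class not in classes:
        positive_class = classes[0]
    prototype = epochs.epochs[y == positive_class].mean(axis=0)
    covs = _covariances(epochs, prototype, shrinkage)
    means = {}
    for c in classes:
        group = covs[y == c]
        if metric == "riemannian":
            means[c] = geometric_mean(list(group))
        else:
            means[c] = group.mean(axis=0)
    return MdmModel(
        classes=classes,
        means=means,
        prototype=prototype,
        metric=metric,
        shrinkage=shrinkage,
        positive_class=positive_class,
    )


def predict_and_score(
    model: MdmModel, epochs: EpochSet
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center labels and continuous oddball scores for new epochs.

    The score is ``d(x, mean_negative) - d(x, mean_positive)`` (larger =
    more oddball-like), suitable for ranking/AUC.  Exact ties are broken
    toward the lexicographically first class and flagged with a warning.
    """
    if epochs.epochs.shape[1] != model.prototype.shape[0] or (
        epochs.epochs.shape[2] != model.prototype.shape[1]
    ):
        raise ValueError(
            f"epoch shape {epochs.epochs.shape[1:]} does not match the model "
            f"prototype {model.prototype.shape}"
        )
    covs = _covariances(epochs, model.prototype, model.shrinkage)
    dists = np.array(
        [[model.distance(c, model.means[cls]) for cls in model.classes] for c in covs]
    )
    ties = np.isclose(dists.min(axis=1, keepdims=True), dists).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} equidistant epoch(s); ties broken "
                      "toward the lexicographically first class", stacklevel=2)
    labels = np.asarray(model.classes, dtype=object)[dists.argmin(axis=1)]
    pos = model.classes.index(model.positive_class)
    negatives = [i for i in range(len(model.classes)) if i != pos]
    scores = dists[:, negatives].min(axis=1) - dists[:, pos]
    return labels, scores


def rank_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one epoch of each class")
    ranks = stats.rankdata(scores)
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def chi_square_confusion(confusion: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 confusion table.

    A table with an empty row or column margin (e.g. a class never
    predicted) carries no measurable association; it yields (0.0, 1.0).
    """
    obs = np.asarray(confusion, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"confusion table must be 2x2, got {obs.shape}")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


@dataclass
class ClassifierReport:
    """Pooled out-of-fold performance of the MDM classifier."""

    accuracy: float
    auc: float
    confusion: np.ndarray  # rows: true class (sorted), cols: predicted
    chi2: float
    chi2_p: float
    classes: tuple[str, ...]
    k_folds: int
    seed: int | None
    n_epochs: int = 0
    metric: str = "riemannian"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
            "classes": list(self.classes),
            "k_folds": self.k_folds,
            "seed": self.seed,
            "n_epochs": self.n_epochs,
            "metric": self.metric,
        }


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled stratified fold assignment; returns k index arrays."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(set(y.tolist())):
        idx = rng.permutation(np.flatnonzero(y == c))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def evaluate_cv(
    epochs: EpochSet,
    labels: Sequence[str] | None = None,
    k_folds: int = 5,
    seed: int | None = 0,
    metric: str = "riemannian",
    shrinkage: float = 0.1,
    positive_class: str = "oddball",
) -> ClassifierReport:
    """Stratified k-fold cross-validation of the MDM classifier.

    Prototype and class centers are re-fit on every training split; the
    out-of-fold predictions are pooled into one confusion matrix from which
    accuracy, rank-based AUC and the Pearson chi-square statistic are
    computed.
    """
    y = np.asarray(labels if labels is not None else epochs.labels)
    classes = tuple(sorted(set(y.tolist())))
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < k_folds:
        raise ValueError(
            f"every class must have >= k_folds={k_folds} epochs, got {counts}"
        )
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k_folds, rng)
    pred = np.empty(epochs.n_epochs, dtype=object)
    score = np.empty(epochs.n_epochs)
    for test_idx in folds:
        train_mask = np.ones(epochs.n_epochs, dtype=bool)
        train_mask[test_idx] = False
        train = EpochSet(
            epochs=epochs.epochs[train_mask],
            times=epochs.times,
            labels=y[train_mask],
            fs=epochs.fs,
            channel_names=epochs.channel_names,
        )
        test = EpochSet(
            epochs=epochs.epochs[test_idx],
            times=epochs.times,
            labels=y[test_idx],
            fs=epochs.fs,
            channel_names=epochs.channel_names,
        )
        model = fit_mdm(
            train, metric=metric, shrinkage=shrinkage, positive_class=positive_class
        )
        pred[test_idx], score[test_idx] = predict_and_score(model, test)

    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for i, true_c in enumerate(classes):
        for j, pred_c in enumerate(classes):
            confusion[i, j] = int(np.sum((y == true_c) & (pred == pred_c)))
    accuracy = float(np.trace(confusion)) / epochs.n_epochs
    pos = positive_class if positive_class in classes else classes[0]
    auc = rank_auc(score, y == pos)
    chi2, chi2_p = chi_square_confusion(confusion) if len(classes) == 2 else (np.nan, np.nan)
    return ClassifierReport(
        accuracy=accuracy,
        auc=auc,
        confusion=confusion,
        chi2=chi2,
        chi2_p=chi2_p,
        classes=classes,
        k_folds=k_folds,
        seed=seed,
        n_epochs=epochs.n_epochs,
        metric=metric,
    )
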