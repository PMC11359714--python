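"""Reconstruction metrics and the downstream motor-imagery quality check.

Reconstruction fidelity alone does not show that interpolated channels are
*useful*; the downstream check asks whether a standard four-class motor
imagery decoder works better on the reconstructed high-density montage than
on the low-density recording it came from.  The decoder is the classical
pipeline: mu/beta band-pass, one-versus-rest Common Spatial Patterns for
feature extraction, and a regularized linear discriminant per class.

CSP solves, for class c against the rest, the generalized eigenproblem

    Sigma_c w = lambda (Sigma_c + Sigma_rest) w

on trace-normalized average trial covariances; the eigenvectors with the m
largest and m smallest eigenvalues maximize/minimize the class-c variance
ratio.  Features are the log of the normalized variances of the filtered
epoch.  Equal class covariances give all eigenvalues 1/2 (no contrast).

Also provided: scalp topographic grids (inverse-distance-squared
interpolation of per-electrode values onto a planar grid with contour
levels), used to inspect the spatial coherence of reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .montage import Montage
from .preprocess import CLASSES, EpochSet, bandpass_array, split_rounds

__all__ = [
    "rmse",
    "csp_fit",
    "csp_generalized_eigenvalues",
    "csp_features",
    "CSPModel",
    "OVRClassifier",
    "ConfusionMatrix",
    "ovr_train",
    "ovr_predict",
    "ClassifyConfig",
    "compare_densities",
    "accuracy_table",
    "TopoGrid",
    "topogrid",
]


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series (uV)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("series must be nonempty and of equal shape")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def _mean_normalized_cov(epochs: np.ndarray, reg: float) -> np.ndarray:
    """Average trace-normalized trial covariance with ridge regularization."""
    n_ch = epochs.shape[1]
    acc = np.zeros((n_ch, n_ch))
    for x in epochs:
        c = x @ x.T
        acc += c / np.trace(c)
    acc /= len(epochs)
    return acc + reg * (np.trace(acc) / n_ch) * np.eye(n_ch)


def _csp_eig(epochs_A: np.ndarray, epochs_B: np.ndarray, reg: float):
    if len(epochs_A) < 2 or len(epochs_B) < 2:
        raise ValueError("need at least 2 trials per side")
    Sa = _mean_normalized_cov(np.asarray(epochs_A, dtype=float), reg)
    Sb = _mean_normalized_cov(np.asarray(epochs_B, dtype=float), reg)
    evals, evecs = linalg.eigh(Sa, Sa + Sb)
    order = np.argsort(evals)[::-1]  # descending eigenvalue
    return evals[order], evecs[:, order]


def csp_generalized_eigenvalues(epochs_A, epochs_B, reg: float = 1e-6) -> np.ndarray:
    """All generalized eigenvalues of the A-vs-B CSP pencil, descending."""
    evals, _ = _csp_eig(epochs_A, epochs_B, reg)
    return evals


def csp_fit(epochs_A, epochs_B, m: int = 3, reg: float = 1e-6) -> np.ndarray:
    """CSP spatial filters for A vs B: (2m x channels).

    Rows are the generalized eigenvectors with the m largest eigenvalues
    (maximal A-variance share) followed by the m smallest, in descending
    eigenvalue order.
    """
    evals, evecs = _csp_eig(epochs_A, epochs_B, reg)
    n_ch = evecs.shape[0]
    if 2 * m > n_ch:
        raise ValueError(f"2m = {2 * m} exceeds channel count {n_ch}")
    keep = list(range(m)) + list(range(n_ch - m, n_ch))
    return evecs[:, keep].T


def csp_features(filters: np.ndarray, epoch: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of one (channels x samples) epoch."""
    proj = filters @ epoch
    var = proj.var(axis=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance CSP projection")
    return np.log(var / var.sum())


@dataclass
class CSPModel:
    """Per-class one-vs-rest CSP filter banks."""

    filters: dict  # class name -> (2m x channels)
    m: int


@dataclass
class OVRClassifier:
    """One binary discriminant per class over that class's CSP features.

    The predicted label is the argmax of the class scores; exact ties go to
    the lowest class index in the canonical order (left, right, tongue,
    foot).
    """

    csp: CSPModel
    scorers: dict  # class name -> fitted LinearDiscriminantAnalysis
    classes: tuple[str, ...] = CLASSES


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # 4x4, rows = true, cols = predicted
    classes: tuple[str, ...]

    @property
    def per_class_accuracy(self) -> np.ndarray:
        rows = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, np.diag(self.counts) / rows, np.nan)

    @property
    def total_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def ovr_train(epochs: EpochSet, m: int = 3, reg: float = 1e-6) -> OVRClassifier:
    """Fit the one-versus-rest CSP + discriminant pipeline."""
    present = set(epochs.labels.tolist())
    missing = set(CLASSES) - present
    if missing:
        raise ValueError(f"classes absent from training set: {sorted(missing)}")
    filters, scorers = {}, {}
    for cls_name in CLASSES:
        is_c = epochs.labels == cls_name
        filt = csp_fit(epochs.data[is_c], epochs.data[~is_c], m=m, reg=reg)
        feats = np.stack([csp_features(filt, x) for x in epochs.data])
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(feats, is_c.astype(int))
        filters[cls_name] = filt
        scorers[cls_name] = lda
    return OVRClassifier(csp=CSPModel(filters=filters, m=m), scorers=scorers)


def ovr_predict(clf: OVRClassifier, epochs: EpochSet):
    """Predict labels; returns (labels, ConfusionMatrix, per-class acc, total)."""
    scores = np.empty((epochs.n_trials, len(clf.classes)))
    for j, cls_name in enumerate(clf.classes):
        filt = clf.csp.filters[cls_name]
        feats = np.stack([csp_features(filt, x) for x in epochs.data])
        scores[:, j] = clf.scorers[cls_name].decision_function(feats)
    pred_idx = np.argmax(scores, axis=1)  # argmax takes the lowest on ties
    predicted = np.asarray([clf.classes[j] for j in pred_idx])
    counts = np.zeros((4, 4), dtype=int)
    cls_index = {c: j for j, c in enumerate(clf.classes)}
    for true, pred in zip(epochs.labels, predicted):
        counts[cls_index[true], cls_index[pred]] += 1
    cm = ConfusionMatrix(counts=counts, classes=clf.classes)
    return predicted, cm, cm.per_class_accuracy, cm.total_accuracy


@dataclass(frozen=True)
class ClassifyConfig:
    """Classification-path settings: mu+beta band, m filter pairs, and the
    feature window relative to the cue (the paradigm's imagery period,
    skipping the reaction-time onset)."""

    band: tuple[float, float] = (8.0, 30.0)
    m: int = 3
    reg: float = 1e-6
    window_s: tuple[float, float] = (0.5, 3.5)
    n_folds: int = 5


def _prepare(epochs: EpochSet, cfg: ClassifyConfig) -> EpochSet:
    from dataclasses import replace

    data = bandpass_array(epochs.data, cfg.band[0], cfg.band[1], epochs.fs)
    lo = epochs.cue_sample + int(round(cfg.window_s[0] * epochs.fs))
    hi = epochs.cue_sample + int(round(cfg.window_s[1] * epochs.fs))
    if not 0 <= lo < hi <= data.shape[2]:
        raise ValueError("feature window outside epoch")
    return replace(epochs, data=data[:, :, lo:hi], cue_sample=0)


def _crossval_confusion(epochs: EpochSet, cfg: ClassifyConfig) -> ConfusionMatrix:
    prepared = _prepare(epochs, cfg)
    counts = np.zeros((4, 4), dtype=int)
    for fold in range(1, cfg.n_folds + 1):
        train_e, test_e = split_rounds(prepared, fold)
        clf = ovr_train(train_e, m=cfg.m, reg=cfg.reg)
        _, cm, _, _ = ovr_predict(clf, test_e)
        counts += cm.counts
    return ConfusionMatrix(counts=counts, classes=CLASSES)


def compare_densities(epoch_sets: dict, cfg: ClassifyConfig = ClassifyConfig()) -> dict:
    """Run the identical decoding pipeline on several epoch sets.

    *epoch_sets* maps a condition name (e.g. ``"18ch"``, ``"bilstm60"``,
    ``"true60"``) to an :class:`EpochSet`; all sets must share trial labels,
    round ids and timing so the round-folds align.  Returns per condition a
    dict with the pooled confusion matrix, per-class accuracies and the
    total accuracy.
    """
    items = list(epoch_sets.items())
    ref = items[0][1]
    for name, ep in items[1:]:
        if (len(ep.labels) != len(ref.labels)
                or np.any(ep.labels != ref.labels)
                or np.any(ep.round_ids != ref.round_ids)):
            raise ValueError(f"epoch set {name!r} misaligned with {items[0][0]!r}")
    out = {}
    for name, ep in items:
        cm = _crossval_confusion(ep, cfg)
        out[name] = {
            "confusion": cm,
            "per_class": dict(zip(CLASSES, cm.per_class_accuracy)),
            "total": cm.total_accuracy,
        }
    return out


def accuracy_table(results: dict) -> pd.DataFrame:
    """Accuracy table (%); rows = conditions, columns = classes + total."""
    rows = {}
    for name, res in results.items():
        row = {c: 100.0 * res["per_class"][c] for c in CLASSES}
        row["total"] = 100.0 * res["total"]
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class TopoGrid:
    """Planar scalp grid of interpolated values with contour levels."""

    grid: np.ndarray  # (grid_n, grid_n), NaN outside the head disk
    x: np.ndarray
    y: np.ndarray
    levels: np.ndarray
    head_radius: float


def topogrid(values, montage: Montage, grid_n: int = 64,
             n_contours: int = 6) -> TopoGrid:
    """Interpolate one value per electrode onto a head-disk grid.

    Inverse-distance-squared weighting of the electrode values at every
    grid node inside the head disk (radius = the montage's outermost
    electrode), with exact passthrough at nodes coincident with an
    electrode; contour levels are equally spaced over the value range.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage),):
        raise ValueError("need exactly one value per montage electrode")
    if len(montage) < 3:
        raise ValueError("need at least 3 electrodes")
    pos = montage.positions2d
    radius = float(np.linalg.norm(pos, axis=1).max())
    axis = np.linspace(-radius, radius, grid_n)
    gx, gy = np.meshgrid(axis, axis)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    grid = np.empty(len(pts))
    exact = d2 == 0.0
    hit = exact.any(axis=1)
    grid[hit] = values[np.argmax(exact[hit], axis=1)]
    w = 1.0 / d2[~hit]
    grid[~hit] = (w @ values) / w.sum(axis=1)
    grid[np.hypot(pts[:, 0], pts[:, 1]) > radius] = np.nan
    grid = grid.reshape(grid_n, grid_n)
    levels = np.linspace(values.min(), values.max(), n_contours)
    return TopoGrid(grid=grid, x=axis, y=axis, levels=levels, head_radius=radius)
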