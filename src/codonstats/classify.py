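"""Taxonomic classification of coding sequences from codon-usage features.

The workflow mirrors composition-based metagenomic binning: per-sequence
RSCU vectors are reduced by mean-centred PCA, the number of retained
components is chosen at the elbow of the explained-variance profile
(Scree heuristic), and a radial-basis SVM with inverse-frequency class
weights is trained on the retained scores. Held-out sequences are
projected with the training loadings and scored per class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .rscu import RSCUVector, rscu_matrix

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

DEFAULT_COST_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)
DEFAULT_LENGTH_BINS = (100, 200, 500, 1000, float("inf"))


@dataclass
class PCAModel:
    """Mean-centred PCA with a fixed component-sign convention.

    Signs are normalized so the largest-magnitude loading of every
    component is positive, making scores reproducible across fits.
    ``k_retained`` components (Scree elbow by default) feed the classifier;
    all components are kept for reconstruction.
    """

    loadings: np.ndarray            # (n_components, n_features)
    center: np.ndarray
    scores: np.ndarray              # training scores, all components
    explained_variance_ratio: np.ndarray
    k_retained: int
    feature_names: Tuple[str, ...]

    def transform(self, X: np.ndarray, retained_only: bool = True) -> np.ndarray:
        scores = (np.asarray(X, dtype=float) - self.center) @ self.loadings.T
        return scores[:, : self.k_retained] if retained_only else scores

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings[: scores.shape[1]] + self.center

    @property
    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.loadings).tobytes())
        h.update(np.ascontiguousarray(self.center).tobytes())
        return h.hexdigest()[:16]


@dataclass
class DomainModel:
    """Trained SVM over PCA scores, bound to the PCA that produced them."""

    svm: SVC
    classes: Tuple[str, ...]
    params: Dict[str, float]
    class_weights: Dict[str, float]
    pca_fingerprint: str
    format_version: int = MODEL_FORMAT_VERSION


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    best_params: Dict[str, float]

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


@dataclass
class EvalReport:
    accuracy: float
    confusion: pd.DataFrame
    roc: Dict[str, Dict[str, np.ndarray]]   # class -> {fpr, tpr, auc}
    length_bin_accuracy: pd.DataFrame

    @property
    def auc_by_class(self) -> Dict[str, float]:
        return {cls: float(r["auc"]) for cls, r in self.roc.items()}


def training_matrix(
    vectors: Sequence[RSCUVector],
    labels: Sequence[str],
    max_imputed_fraction: float = 0.30,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Stack vectors into a feature matrix, dropping mostly-imputed rows.

    Sequences whose vectors have more than ``max_imputed_fraction`` of
    their synonymous families imputed carry imputation rather than signal
    (typically very short CDS) and are excluded from training.
    """
    keep = [i for i, v in enumerate(vectors)
            if v.imputed_family_fraction <= max_imputed_fraction]
    if len(keep) < len(vectors):
        logger.info("excluded %d/%d vectors with > %.0f%% imputed families",
                    len(vectors) - len(keep), len(vectors), 100 * max_imputed_fraction)
    mat = rscu_matrix([vectors[i] for i in keep])
    return mat, np.asarray([labels[i] for i in keep])


def scree_retain(explained_variance: Sequence[float], max_k: Optional[int] = None) -> int:
    """Elbow of a non-increasing explained-variance profile.

    The elbow is the component preceding the point of maximal acceleration
    (largest second difference) of the profile; a flat profile has no elbow
    and returns 1 with a warning.
    """
    ev = np.asarray(explained_variance, dtype=float)
    if ev.size < 3:
        return 1
    second_diff = ev[:-2] - 2 * ev[1:-1] + ev[2:]
    if np.allclose(second_diff, 0):
        warnings.warn("no elbow in explained-variance profile; retaining 1 component")
        return 1
    k = int(np.argmax(second_diff)) + 1
    if max_k is not None:
        k = min(k, max_k)
    return max(k, 1)


def fit_pca(
    matrix: pd.DataFrame,
    k_retained: Optional[int] = None,
    max_k: Optional[int] = None,
) -> PCAModel:
    """Mean-centred PCA of an RSCU feature matrix.

    ``k_retained`` defaults to the Scree elbow of the explained-variance
    profile. Raises on a constant matrix (no variance to decompose).
    """
    X = matrix.values.astype(float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix: no variance")
    pca = PCA()
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # sign convention: largest-|loading| entry of each component is positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    k = k_retained if k_retained is not None else scree_retain(
        pca.explained_variance_ratio_, max_k=max_k)
    return PCAModel(
        loadings=loadings,
        center=pca.mean_,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        k_retained=int(k),
        feature_names=tuple(matrix.columns),
    )


def _inverse_frequency_weights(labels: np.ndarray) -> Dict[str, float]:
    classes, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    return {c: n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def train_classifier(
    scores: np.ndarray,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    pca_fingerprint: str = "",
) -> Tuple[DomainModel, CVResult]:
    """Grid-tuned RBF SVM with inverse-class-frequency weights.

    Hyperparameters (cost C, kernel width gamma) are chosen by grid search
    with an inner 3-fold CV; the chosen model is then validated with
    stratified ``folds``-fold cross-validation, and refit on all data with
    probability estimates enabled. Deterministic given ``seed``.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes")
    weights = _inverse_frequency_weights(y)
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf", class_weight=weights),
        {"C": list(cost_grid), "gamma": list(gamma_grid)},
        cv=inner, scoring="accuracy", n_jobs=1)
    search.fit(scores, y)
    best = {"C": float(search.best_params_["C"]),
            "gamma": float(search.best_params_["gamma"])}
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1)
    fold_acc = cross_val_score(
        SVC(kernel="rbf", class_weight=weights, **best), scores, y,
        cv=outer, scoring="accuracy", n_jobs=1)
    final = SVC(kernel="rbf", class_weight=weights, probability=True,
                random_state=seed, **best)
    final.fit(scores, y)
    model = DomainModel(
        svm=final,
        classes=tuple(sorted(np.unique(y))),
        params=best,
        class_weights={str(k): float(v) for k, v in weights.items()},
        pca_fingerprint=pca_fingerprint,
    )
    return model, CVResult(fold_accuracies=fold_acc, best_params=best)


def _check_pairing(model: DomainModel, pca: PCAModel) -> None:
    if model.pca_fingerprint and model.pca_fingerprint != pca.fingerprint:
        raise ValueError("model/PCA version mismatch: the classifier was trained "
                         "on scores from a different PCA")


def predict(
    model: DomainModel, pca: PCAModel, matrix: pd.DataFrame
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Project vectors with the training PCA and classify them.

    Returns predicted labels and per-class probabilities (rows sum to 1).
    The label is the probability argmax, with alphabetical tie-break (the
    class columns are sorted).
    """
    _check_pairing(model, pca)
    if matrix.shape[1] != len(pca.feature_names):
        raise ValueError(
            f"feature dimension mismatch: {matrix.shape[1]} != {len(pca.feature_names)}")
    scores = pca.transform(matrix.values)
    raw = model.svm.predict_proba(scores)
    prob = pd.DataFrame(raw, index=matrix.index, columns=model.svm.classes_)
    prob = prob[sorted(prob.columns)]
    labels = prob.columns.values[np.argmax(prob.values, axis=1)]
    return labels, prob


def evaluate(
    model: DomainModel,
    pca: PCAModel,
    matrix: pd.DataFrame,
    labels: Sequence[str],
    lengths_nt: Optional[Sequence[float]] = None,
    length_bins: Sequence[float] = DEFAULT_LENGTH_BINS,
) -> EvalReport:
    """Held-out evaluation: accuracy, per-class one-vs-rest ROC/AUC, and
    accuracy stratified by sequence length (default bins 100-200, 200-500,
    500-1000, 1000+ nt). Classes absent from the test labels have their
    ROC omitted with a warning."""
    y = np.asarray(labels)
    pred, prob = predict(model, pca, matrix)
    accuracy = float((pred == y).mean())
    classes = sorted(model.classes)
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=classes), index=classes, columns=classes)
    roc: Dict[str, Dict[str, np.ndarray]] = {}
    for cls in classes:
        mask = y == cls
        if mask.sum() == 0 or mask.all():
            warnings.warn(f"class {cls} absent (or exclusive) in test set; ROC omitted")
            continue
        fpr, tpr, _ = roc_curve(mask.astype(int), prob[cls].values)
        roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": auc(fpr, tpr)}
    if lengths_nt is not None:
        L = np.asarray(lengths_nt, dtype=float)
        rows = []
        edges = list(length_bins)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (L >= lo) & (L < hi)
            label = f"{int(lo)}-{int(hi)}" if np.isfinite(hi) else f"{int(lo)}+"
            acc = float((pred[sel] == y[sel]).mean()) if sel.any() else np.nan
            rows.append((label, int(sel.sum()), acc))
        length_acc = pd.DataFrame(rows, columns=["length_bin", "n", "accuracy"])
    else:
        length_acc = pd.DataFrame(columns=["length_bin", "n", "accuracy"])
    return EvalReport(accuracy=accuracy, confusion=conf, roc=roc,
                      length_bin_accuracy=length_acc)


def save_model(path, model: DomainModel, pca: PCAModel) -> None:
    """Serialize the paired PCA + classifier to one archive."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model, "pca": pca}, path)


def load_model(path) -> Tuple[DomainModel, PCAModel]:
    bundle = joblib.load(path)
    if bundle.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {bundle.get('format_version')!r}")
    return bundle["model"], bundle["pca"]
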