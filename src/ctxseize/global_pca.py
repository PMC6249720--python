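"""Global features: top-k PCA of the concatenated all-channel scalogram vectors.

The "global" context treats the whole multi-channel scalogram of a fragment
as one long vector and projects it onto its top-k principal components,
discarding redundant and irrelevant inter-channel variation.  k can be fixed
(default 10) or chosen by cross-validated accuracy of a linear-SVM probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

DEFAULT_K = 10


@dataclass
class PCAModel:
    mean: np.ndarray              # (d,)
    components: np.ndarray        # (k, d), orthonormal rows
    explained_variance: np.ndarray  # nonincreasing, length k
    k: int


@dataclass
class GlobalFeature:
    scores: np.ndarray  # (k,)


def _as_matrix(X) -> np.ndarray:
    rows = [np.ravel(getattr(v, "values", v)) for v in X]
    return np.asarray(rows, dtype=np.float64)


def fit_gpca(X, k: int = DEFAULT_K) -> PCAModel:
    """Centered PCA keeping the first k components by explained variance."""
    M = _as_matrix(X)
    n, d = M.shape
    if k < 1 or k >= min(n, d) or k > n - 1:
        raise ValueError(f"k={k} out of range for data of shape {M.shape}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(M)
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        k=k,
    )


def transform_gpca(model: PCAModel, x: np.ndarray) -> GlobalFeature:
    """Project one concatenated scalogram vector: scores = components (x - mean)."""
    x = np.ravel(getattr(x, "values", x))
    if x.shape[0] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: vector has {x.shape[0]}, model expects "
            f"{model.mean.shape[0]}"
        )
    return GlobalFeature(model.components @ (x - model.mean))


def transform_gpca_batch(model: PCAModel, X) -> np.ndarray:
    M = _as_matrix(X)
    return (M - model.mean) @ model.components.T


def select_k(
    X,
    labels: Sequence,
    candidates: Sequence[int],
    eval_protocol: str = "stratified5",
    seed: int = 0,
) -> int:
    """Pick the component count maximizing linear-probe validation accuracy.

    The probe is PCA -> standardize -> linear SVM inside each fold (no
    leakage).  ``eval_protocol`` is ``"stratified5"`` (default) or ``"loo"``
    for exact leave-one-out.  Ties break to the smallest k.  Folds that end
    up single-class are skipped with a warning.
    """
    candidates = sorted(set(int(k) for k in candidates))
    if not candidates:
        raise ValueError("no candidate k values given")
    if len(candidates) == 1:
        return candidates[0]
    M = _as_matrix(X)
    y = np.asarray(labels)
    if eval_protocol == "stratified5":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        folds = list(splitter.split(M, y))
    elif eval_protocol == "loo":
        folds = list(LeaveOneOut().split(M, y))
    else:
        raise ValueError(f"unknown eval_protocol {eval_protocol!r}")

    best_k, best_acc = None, -1.0
    for k in candidates:
        if k > min(M.shape[1], M.shape[0] - 1):
            continue
        correct = total = 0
        for tr, va in folds:
            if len(np.unique(y[tr])) < 2:
                warnings.warn("skipping single-class fold in select_k", stacklevel=2)
                continue
            probe = make_pipeline(
                PCA(n_components=k, svd_solver="full"),
                StandardScaler(),
                LinearSVC(random_state=seed),
            )
            probe.fit(M[tr], y[tr])
            correct += int((probe.predict(M[va]) == y[va]).sum())
            total += len(va)
        acc = correct / total if total else 0.0
        if acc > best_acc:  # strict >: ties keep the smaller k
            best_k, best_acc = k, acc
    if best_k is None:
        raise ValueError("no feasible candidate k for this dataset")
    return best_k


def save_gpca(model: PCAModel, path: str | Path) -> None:
    np.savez_compressed(
        path,
        mean=model.mean,
        components=model.components,
        explained_variance=model.explained_variance,
        k=np.array(model.k),
    )


def load_gpca(path: str | Path) -> PCAModel:
    with np.load(path) as npz:
        return PCAModel(
            mean=npz["mean"],
            components=npz["components"],
            explained_variance=npz["explained_variance"],
            k=int(npz["k"]),
        )
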