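"""Hybrid window/feature optimization.

Features are ranked once by information gain; then window geometry
(upstream length Lu, downstream length Ld, total L = Lu + 1 + Ld) and the
number of top-ranked features F are grid-searched, scoring every
combination by 10-fold cross-validated AUC of the ten-forest ensemble.
For each geometry the best AUC over the F sweep and its feature subset
are stored; the returned optimum is the argmax over geometries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .encoding import EncodingConfig, encode_windows, feature_names
from .errors import ValidationError
from .metrics import roc_auc
from .model import score_samples, train_ensemble

logger = logging.getLogger(__name__)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def information_gain(feature: np.ndarray, labels: np.ndarray, bins: int = 10) -> float:
    """Reduction in label entropy after discretizing the feature.

    Binary (or few-valued) features are used as-is; continuous features
    are split into up to ``bins`` equal-frequency bins.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(feature)
    if len(uniq) <= bins:
        binned = np.searchsorted(uniq, feature)
    else:
        edges = np.unique(np.quantile(feature, np.linspace(0, 1, bins + 1)[1:-1]))
        binned = np.digitize(feature, edges)
    h = _entropy(labels)
    cond = 0.0
    n = len(labels)
    for b in np.unique(binned):
        mask = binned == b
        cond += mask.sum() / n * _entropy(labels[mask])
    return h - cond


def rank_features_infogain(
    X: np.ndarray,
    labels: np.ndarray,
    names: Sequence[str],
    bins: int = 10,
) -> list[str]:
    """Feature names sorted by decreasing information gain; ties broken by
    the canonical feature order."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("labels contain a single class")
    if len(set(names)) != len(names):
        raise ValidationError("feature names must be unique")
    gains = np.array([information_gain(X[:, j], labels, bins) for j in range(X.shape[1])])
    # stable sort on -gain preserves canonical order among ties
    order = np.argsort(-gains, kind="stable")
    return [names[j] for j in order]


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    seed: int,
    folds: int = 10,
    feature_names_: Sequence[str] | None = None,
    train_kwargs: dict | None = None,
    fold_feature_selector: Callable | None = None,
) -> tuple[float, np.ndarray, np.ndarray, list[float]]:
    """Stratified k-fold cross-validation of the ensemble.

    Per fold, the ensemble is trained on the other folds and scores the
    held-out samples.  Returns (mean of the per-fold AUCs, pooled
    out-of-fold scores, the corresponding labels in pooled order, the
    per-fold AUCs).  Every sample receives exactly one out-of-fold score.

    ``fold_feature_selector(X_train, y_train)`` may return column indices
    to restrict features per fold (leakage-free re-ranking).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    for cls in (0, 1):
        if (labels == cls).sum() < folds:
            raise ValidationError(f"need at least {folds} samples of class {cls}")
    train_kwargs = dict(train_kwargs or {})

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    pooled_scores = np.empty(len(labels))
    pooled_mask = np.zeros(len(labels), dtype=bool)
    fold_aucs = []
    for k, (train_idx, test_idx) in enumerate(skf.split(X, labels)):
        cols = np.arange(X.shape[1])
        if fold_feature_selector is not None:
            cols = np.asarray(
                fold_feature_selector(X[train_idx], labels[train_idx])
            )
        X_pos = X[train_idx][labels[train_idx] == 1][:, cols]
        X_neg = X[train_idx][labels[train_idx] == 0][:, cols]
        model = train_ensemble(
            X_pos, X_neg, seed=seed + 1000 * (k + 1),
            feature_names=(
                [feature_names_[c] for c in cols] if feature_names_ is not None else None
            ),
            **train_kwargs,
        )
        s = score_samples(model, X[test_idx][:, cols])
        pooled_scores[test_idx] = s
        pooled_mask[test_idx] = True
        fold_aucs.append(roc_auc(s, labels[test_idx]))
    assert pooled_mask.all(), "every sample must receive one out-of-fold score"
    return float(np.mean(fold_aucs)), pooled_scores, labels, fold_aucs


@dataclass
class OptimizationResult:
    auc_matrix: dict[tuple[int, int], float]
    feature_matrix: dict[tuple[int, int], list[str]]
    best_geometry: tuple[int, int]
    best_features: list[str]
    best_auc: float


def default_feature_grid(n_features: int) -> list[int]:
    """Geometric grid 2, 4, 8, ... capped at the full feature count."""
    grid = []
    f = 2
    while f < n_features:
        grid.append(f)
        f *= 2
    grid.append(n_features)
    return grid


def optimize_model(
    windows: Sequence[str],
    labels: Sequence[int],
    seed: int,
    L_values: Sequence[int] | None = None,
    geometries: Sequence[tuple[int, int]] | None = None,
    feature_grid: Sequence[int] | str = "geometric",
    folds: int = 10,
    encoding_config: EncodingConfig | None = None,
    ig_bins: int = 10,
    leakage_free: bool = False,
    train_kwargs: dict | None = None,
) -> OptimizationResult:
    """Grid-search geometry × feature count by cross-validated AUC.

    ``windows`` are full-width labeled windows (odd length, centered on
    the cytosine); each candidate geometry (Lu, Ld) is evaluated on the
    corresponding sub-windows.  By default every L in ``L_values`` expands
    to all (Lu, Ld = L-1-Lu) with Lu from 1 to L-2; pass ``geometries``
    to restrict.  ``feature_grid`` is 'geometric' (2, 4, 8, ... all),
    'exhaustive' (every integer from 2), or an explicit list of counts.
    With ``leakage_free`` the information-gain ranking is recomputed
    inside each training fold instead of once per geometry.
    """
    windows = list(windows)
    labels = np.asarray(labels).astype(int)
    if not windows:
        raise ValidationError("empty dataset")
    full_L = len(windows[0])
    if any(len(w) != full_L for w in windows):
        raise ValidationError("windows must share a common (maximal) length")
    center = full_L // 2
    cfg = encoding_config or EncodingConfig()

    if geometries is None:
        if L_values is None:
            L_values = range(5, full_L + 1, 2)
        geometries = [
            (lu, L - 1 - lu)
            for L in L_values
            for lu in range(1, L - 1)
            if L - 1 - lu >= 1
        ]
    geometries = [
        (lu, ld) for (lu, ld) in geometries if lu <= center and ld <= center
    ]
    if not geometries:
        raise ValidationError("empty geometry grid")

    auc_matrix: dict[tuple[int, int], float] = {}
    feature_matrix: dict[tuple[int, int], list[str]] = {}
    for lu, ld in geometries:
        sub = [w[center - lu : center + ld + 1] for w in windows]
        L = lu + 1 + ld
        X = encode_windows(sub, cfg)
        names = feature_names(L, cfg, upstream=lu)
        n_feat = X.shape[1]

        if feature_grid == "geometric":
            grid = default_feature_grid(n_feat)
        elif feature_grid == "exhaustive":
            grid = list(range(2, n_feat + 1))
        else:
            grid = sorted({min(int(f), n_feat) for f in feature_grid})
        if not grid:
            raise ValidationError("empty feature grid")

        ranked = rank_features_infogain(X, labels, names, bins=ig_bins)
        name_to_col = {nm: j for j, nm in enumerate(names)}

        best_auc_here = -np.inf
        best_feats_here: list[str] = []
        for F in grid:
            if leakage_free:
                def selector(Xt, yt, F=F):
                    rk = rank_features_infogain(Xt, yt, names, bins=ig_bins)
                    return [name_to_col[nm] for nm in rk[:F]]

                auc, *_ = cross_validate(
                    X, labels, seed=seed, folds=folds,
                    fold_feature_selector=selector, train_kwargs=train_kwargs,
                )
                top = ranked[:F]
            else:
                top = ranked[:F]
                cols = [name_to_col[nm] for nm in top]
                auc, *_ = cross_validate(
                    X[:, cols], labels, seed=seed, folds=folds,
                    train_kwargs=train_kwargs,
                )
            if auc > best_auc_here:
                best_auc_here = auc
                best_feats_here = list(top)
        auc_matrix[(lu, ld)] = best_auc_here
        feature_matrix[(lu, ld)] = best_feats_here
        logger.info("geometry Lu=%d Ld=%d best AUC %.4f", lu, ld, best_auc_here)

    best_geometry = max(auc_matrix, key=lambda g: auc_matrix[g])
    return OptimizationResult(
        auc_matrix=auc_matrix,
        feature_matrix=feature_matrix,
        best_geometry=best_geometry,
        best_features=feature_matrix[best_geometry],
        best_auc=auc_matrix[best_geometry],
    )


def write_auc_matrix(result: OptimizationResult, path) -> None:
    """AUC matrix as TSV: rows Lu, columns Ld."""
    import pandas as pd

    lus = sorted({lu for lu, _ in result.auc_matrix})
    lds = sorted({ld for _, ld in result.auc_matrix})
    df = pd.DataFrame(index=lus, columns=lds, dtype=float)
    for (lu, ld), auc in result.auc_matrix.items():
        df.loc[lu, ld] = auc
    df.index.name = "Lu"
    df.to_csv(path, sep="\t")
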