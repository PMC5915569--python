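"""The ten-forest ensemble classifier with confidence-mode thresholds.

Training data for m5C prediction is heavily imbalanced (negatives are
drawn 10 per positive), so instead of one classifier on the full set the
negatives are split into 10 near-equal parts and ten random forests (100
trees each) are trained, each on all positives plus one negative part.
A sample's score is the arithmetic mean of the ten forests' positive-class
probabilities.  Four operating thresholds are anchored at 99/95/90/85%
empirical specificity on pooled cross-validation negative scores; they
define the VH/H/N/L confidence modes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .encoding import EncodingConfig
from .errors import DegenerateSplitError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Confidence modes in decreasing stringency, with their anchored specificity.
MODE_SPECIFICITY = {"VHmode": 0.99, "HMode": 0.95, "NMode": 0.90, "LMode": 0.85}
MODES = tuple(MODE_SPECIFICITY)

N_FORESTS = 10
N_TREES = 100


@dataclass
class EnsembleModel:
    forests: list
    selected_features: list[str]
    upstream: int
    downstream: int
    thresholds: dict[str, float] = field(default_factory=dict)
    encoding_config: EncodingConfig = field(default_factory=EncodingConfig)
    metadata: dict = field(default_factory=dict)

    @property
    def window_length(self) -> int:
        return self.upstream + 1 + self.downstream


def _dataset_digest(X_pos: np.ndarray, X_neg: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X_pos, dtype=float).tobytes())
    h.update(np.ascontiguousarray(X_neg, dtype=float).tobytes())
    return h.hexdigest()[:16]


def train_ensemble(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    seed: int,
    feature_names: Sequence[str] | None = None,
    upstream: int = 5,
    downstream: int = 5,
    encoding_config: EncodingConfig | None = None,
    n_forests: int = N_FORESTS,
    n_trees: int = N_TREES,
    max_features: str | int | float = "sqrt",
) -> EnsembleModel:
    """Train the balanced-split forest ensemble.

    The negatives are shuffled under ``seed`` and split into ``n_forests``
    near-equal parts (earlier parts one larger when the division is not
    exact); forest i is trained on all positives plus negative part i.
    Each forest has ``n_trees`` trees with bootstrap resampling and random
    feature subsetting at each split.
    """
    X_pos = np.asarray(X_pos, dtype=float)
    X_neg = np.asarray(X_neg, dtype=float)
    if X_pos.ndim != 2 or X_neg.ndim != 2 or X_pos.shape[1] != X_neg.shape[1]:
        raise ValidationError("positive/negative matrices must be 2-D with equal width")
    if len(X_pos) == 0 or len(X_neg) < n_forests:
        raise DegenerateSplitError(
            "need at least one positive and one negative per forest"
        )
    ratio = len(X_neg) / len(X_pos)
    if not 5 <= ratio <= 20:
        logger.warning(
            "negative:positive ratio %.1f far from the intended 10:1", ratio
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X_neg))
    parts = np.array_split(order, n_forests)
    forest_seeds = np.random.SeedSequence(seed).generate_state(n_forests) % (2**31)

    forests = []
    for i, part in enumerate(parts):
        X = np.vstack([X_pos, X_neg[part]])
        y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(part))])
        if len(np.unique(y)) < 2:
            raise DegenerateSplitError(f"training split {i} has a single class")
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            bootstrap=True,
            random_state=int(forest_seeds[i]),
            n_jobs=1,
        )
        clf.fit(X, y)
        forests.append(clf)

    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X_pos.shape[1])]
    return EnsembleModel(
        forests=forests,
        selected_features=list(feature_names),
        upstream=upstream,
        downstream=downstream,
        encoding_config=encoding_config or EncodingConfig(),
        metadata={
            "seed": int(seed),
            "dataset_digest": _dataset_digest(X_pos, X_neg),
            "format_version": MODEL_FORMAT_VERSION,
        },
    )


def score_samples(
    model: EnsembleModel,
    X: np.ndarray,
    feature_names: Sequence[str] | None = None,
    return_per_model: bool = False,
):
    """Mean of the ten forests' positive-class probabilities, per sample.

    If ``feature_names`` is given it must match the model's selected
    features (names and order); a mismatch raises :class:`SchemaError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("feature matrix must be 2-D")
    if feature_names is not None and list(feature_names) != model.selected_features:
        raise SchemaError("feature names/order do not match the model")
    if X.shape[1] != len(model.selected_features):
        raise SchemaError(
            f"expected {len(model.selected_features)} features, got {X.shape[1]}"
        )
    per_model = np.empty((len(model.forests), len(X)))
    for i, clf in enumerate(model.forests):
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        per_model[i] = clf.predict_proba(X)[:, pos_col]
    scores = per_model.mean(axis=0)
    if return_per_model:
        return scores, per_model
    return scores


def determine_thresholds(
    scores: Sequence[float], labels: Sequence[int]
) -> dict[str, float]:
    """Specificity-anchored thresholds from pooled out-of-fold scores.

    For each target specificity s the threshold is the smallest value t
    such that the fraction of negative scores strictly below t is >= s
    (the higher-interpolation empirical quantile of the negative scores;
    when even the largest negative score does not satisfy this, the next
    representable float above it).  Classification is score > t, so the
    empirical specificity at t is always >= s on the calibration scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    neg = np.sort(scores[labels == 0])
    if len(neg) == 0:
        raise ValidationError("no negative scores to anchor thresholds")
    n = len(neg)
    thresholds = {}
    for mode, s in MODE_SPECIFICITY.items():
        m = int(np.ceil(s * n))  # need at least m scores strictly below t
        floor_val = neg[m - 1]
        above = neg[neg > floor_val]
        t = float(above[0]) if len(above) else float(np.nextafter(floor_val, np.inf))
        thresholds[mode] = t
    return thresholds


def classify_with_mode(score: float, model_or_thresholds, mode: str) -> str:
    """'positive' iff score is strictly above the mode's threshold."""
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    thresholds = (
        model_or_thresholds.thresholds
        if isinstance(model_or_thresholds, EnsembleModel)
        else model_or_thresholds
    )
    if mode not in thresholds:
        raise ValidationError(f"model has no threshold for {mode}")
    return "positive" if score > thresholds[mode] else "negative"


def modes_passed(score: float, thresholds: Mapping[str, float]) -> list[str]:
    """All confidence modes whose threshold the score exceeds (downward-
    closed: passing VH implies passing H, N and L when thresholds are
    monotone)."""
    return [m for m in MODES if m in thresholds and score > thresholds[m]]


def save_model(model: EnsembleModel, path) -> None:
    """Persist as a single versioned archive file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "forests": model.forests,
        "selected_features": model.selected_features,
        "upstream": model.upstream,
        "downstream": model.downstream,
        "thresholds": model.thresholds,
        "encoding_config": {
            "k_values": list(model.encoding_config.k_values),
            "lam": model.encoding_config.lam,
            "weight": model.encoding_config.weight,
            "property_table": (
                dict(model.encoding_config.property_table)
                if model.encoding_config.property_table is not None
                else None
            ),
            "include_binary": model.encoding_config.include_binary,
            "include_kmer": model.encoding_config.include_kmer,
            "include_psednc": model.encoding_config.include_psednc,
        },
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path) -> EnsembleModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model archive format version {version} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    ec = payload["encoding_config"]
    cfg = EncodingConfig(
        k_values=tuple(ec["k_values"]),
        lam=ec["lam"],
        weight=ec["weight"],
        property_table=ec["property_table"],
        include_binary=ec["include_binary"],
        include_kmer=ec["include_kmer"],
        include_psednc=ec["include_psednc"],
    )
    return EnsembleModel(
        forests=payload["forests"],
        selected_features=payload["selected_features"],
        upstream=payload["upstream"],
        downstream=payload["downstream"],
        thresholds=payload["thresholds"],
        encoding_config=cfg,
        metadata=payload["metadata"],
    )
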