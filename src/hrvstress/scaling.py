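"""Feature normalization regimes and an embedding-based QA check.

Two mutually exclusive regimes are supported:

* **train-zscore** — classical per-fold standardization: means/SDs are
  estimated on the training fold only and re-used for the test fold
  (:class:`TrainZScoreScaler`).
* **personalized longitudinal scaling** — each participant's features are
  z-scored against that participant's own mean/SD computed across *all* of
  their recorded phases and visits (:func:`longitudinal_scale`).  This is a
  within-person rescaling applied before any train/test split; it
  deliberately uses the participant's full record, so it is not a
  fold-safe transformation and must not be combined with train-zscore.

Sample SDs (ddof=1) are used throughout, consistent with the feature
extractor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FEATURE_NAMES
from .errors import InsufficientDataError

__all__ = [
    "TrainZScoreScaler",
    "fit_train_scaler",
    "apply_scaler",
    "longitudinal_scale",
    "embed_2d",
]


class TrainZScoreScaler(TransformerMixin, BaseEstimator):
    """Z-scaling with statistics estimated on the training data only.

    Unlike :class:`sklearn.preprocessing.StandardScaler` this uses the
    sample SD (ddof=1), so transformed training columns have sample SD
    exactly 1.  Zero-variance features pass through as 0 with a warning.

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
    scale_ : ndarray of shape (n_features,)
        Per-feature sample SD; zero-variance features keep scale 1 and are
        recorded in ``constant_mask_``.
    provenance_ : str
        Free-form tag of the training fold the statistics came from.
    """

    def __init__(self, provenance: str = "train"):
        self.provenance = provenance

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_all_finite="allow-nan")
        self.mean_ = np.nanmean(X, axis=0)
        self.scale_ = np.nanstd(X, axis=0, ddof=1)
        self.constant_mask_ = self.scale_ == 0
        if self.constant_mask_.any():
            warnings.warn(
                f"{int(self.constant_mask_.sum())} constant feature(s) in the "
                "training fold; their scaled values are set to 0",
                stacklevel=2,
            )
        self.scale_ = np.where(self.constant_mask_, 1.0, self.scale_)
        self.n_features_in_ = X.shape[1]
        self.provenance_ = self.provenance
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite="allow-nan")
        out = (X - self.mean_) / self.scale_
        out[:, self.constant_mask_] = 0.0
        return out


def fit_train_scaler(train_X) -> TrainZScoreScaler:
    """Fit z-scaling statistics on training samples only."""
    return TrainZScoreScaler().fit(np.asarray(train_X, dtype=float))


def apply_scaler(X, scaler: TrainZScoreScaler) -> np.ndarray:
    """Apply previously fitted training statistics to any samples."""
    return scaler.transform(np.asarray(X, dtype=float))


def longitudinal_scale(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    participant_col: str = "participant",
) -> pd.DataFrame:
    """Personalized longitudinal scaling of a feature table.

    Each participant's values of each feature are z-scored against that
    participant's own mean and sample SD over all of their rows (all phases
    of all visits).  Participants with fewer than 2 rows are dropped with a
    warning; a participant's zero-variance feature scales to 0.
    """
    feature_cols = list(feature_cols or FEATURE_NAMES)
    counts = table.groupby(participant_col, sort=False)[feature_cols[0]].size()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(
            f"dropping {len(singletons)} participant(s) with < 2 records: "
            f"{sorted(map(str, singletons))[:5]}...",
            stacklevel=2,
        )
        table = table[~table[participant_col].isin(singletons)]
    if table.empty:
        raise InsufficientDataError("no participant has >= 2 records")
    out = table.copy()
    grp = out.groupby(participant_col, sort=False)[feature_cols]
    mean = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=1))
    scaled = (out[feature_cols] - mean) / sd
    scaled = scaled.where(sd != 0, 0.0)
    out[feature_cols] = scaled
    return out


def embed_2d(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    label_col: str = "phase",
    perplexity: float = 50.0,
    iterations: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """t-SNE QA embedding of a feature table.

    Returns the 2-D coordinates and the mean silhouette score of the task
    labels in the embedding — a scalar summary of how well the classes
    separate.  Deterministic given the seed.
    """
    feature_cols = list(feature_cols or FEATURE_NAMES)
    X = table[feature_cols].to_numpy(dtype=float)
    if X.shape[0] < 3 * perplexity:
        raise InsufficientDataError(
            f"t-SNE with perplexity {perplexity} needs >= {int(3 * perplexity)} "
            f"samples, got {X.shape[0]}; lower the perplexity"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, max_iter=iterations,
        random_state=seed, init="pca",
    )
    coords = tsne.fit_transform(X)
    score = float(silhouette_score(coords, table[label_col].to_numpy()))
    return coords, score
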