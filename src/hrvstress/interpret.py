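"""Shapley-value feature attribution and cross-repeat importance ranking.

Attributions are exact path-dependent tree Shapley values of the random
forest's positive-class probability, computed on test folds only.  For the
importance ranking, |attribution| is first averaged within each repeat of
the cross-validation and then across repeats; features are ranked in
descending order of that mean (ties broken by canonical feature order).
Both signed means and absolute means are emitted; ranking uses |.|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import HRVStressError
from .features import FEATURE_NAMES
from .treeshap import forest_shap_values

__all__ = ["tree_shapley", "aggregate_importance", "importance_report", "plot_importance"]


def tree_shapley(model, test_X) -> tuple[np.ndarray, float]:
    """Per-row, per-feature Shapley attributions of a fitted tree ensemble.

    Returns ``(attributions, base_value)``; for every row
    ``base_value + attributions.sum()`` equals the model's positive-class
    probability (local accuracy).  Raises for non-tree models.
    """
    est = getattr(model, "best_estimator_", model)
    return forest_shap_values(est, np.asarray(test_X, dtype=float))


def aggregate_importance(
    per_repeat_abs: pd.DataFrame,
    scope: str = "combined",
    regime: str = "raw",
    expected_repeats: int | None = None,
) -> pd.DataFrame:
    """Cross-repeat importance ranking from repeat-level mean |attribution|.

    ``per_repeat_abs`` holds one row per repeat with one column per feature
    (a ``repeat`` column is allowed and ignored).  The report averages
    within-repeat means across repeats, ranks descending, and carries the
    scope (combined / MDD / PD / HC) and scaling regime labels.
    """
    df = per_repeat_abs.copy()
    if expected_repeats is not None and "repeat" in df.columns:
        missing = sorted(set(range(expected_repeats)) - set(df["repeat"].tolist()))
        if missing:
            raise HRVStressError(f"missing attribution repeats: {missing}")
    feat_cols = [c for c in FEATURE_NAMES if c in df.columns]
    if len(feat_cols) != len(FEATURE_NAMES):
        raise HRVStressError(
            f"expected all {len(FEATURE_NAMES)} features, got {len(feat_cols)}"
        )
    means = df[feat_cols].mean(axis=0)
    out = pd.DataFrame(
        {
            "feature": feat_cols,
            "mean_abs_attribution": means.to_numpy(dtype=float),
            "scope": scope,
            "regime": regime,
        }
    )
    # descending rank; ties keep the canonical feature order (stable sort)
    order = np.argsort(-out["mean_abs_attribution"].to_numpy(), kind="stable")
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out.sort_values("rank").reset_index(drop=True)


def importance_report(cv_result, regime: str | None = None) -> pd.DataFrame:
    """Importance table(s) from a CV run that collected attributions.

    Emits one block per scope present in the run (overall plus each
    diagnostic group), concatenated.
    """
    if cv_result.shap_abs is None:
        raise HRVStressError(
            "CV run did not collect Shapley attributions; "
            "rerun with collect_shap=True"
        )
    regime = regime or cv_result.scaling_mode
    blocks = []
    for scope, sub in cv_result.shap_abs.groupby("scope", sort=False):
        label = "combined" if scope == "overall" else str(scope)
        blocks.append(aggregate_importance(sub, scope=label, regime=regime))
    return pd.concat(blocks, ignore_index=True)


def plot_importance(report: pd.DataFrame, scope: str = "combined", ax=None):
    """Horizontal bar plot of mean |attribution|, most important on top."""
    import matplotlib.pyplot as plt

    sub = report[report["scope"] == scope].sort_values("rank", ascending=False)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    ax.barh(sub["feature"], sub["mean_abs_attribution"])
    ax.set_xlabel("mean |Shapley attribution|")
    ax.set_title(f"Feature importance ({scope}, {sub['regime'].iloc[0]})")
    return ax
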