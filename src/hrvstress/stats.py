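"""Within-subject task contrasts (delta-HRV) and between-group comparisons.

delta-HRV is the stress-task value minus the relaxation-task value of a
feature within one participant-visit; it indexes autonomic reactivity to
the stressor.  Group comparisons follow a homogeneity-gated one-way ANOVA:
Brown-Forsythe (median-centred Levene) at alpha = 0.05 decides between
Fisher's ANOVA with Bonferroni-adjusted pairwise t-tests and Welch's ANOVA
with Games-Howell post-hocs.  Effect sizes are eta-squared (from the Fisher
sums-of-squares decomposition in both routes) and pooled-SD Cohen's d for
the pairwise contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .features import FEATURE_NAMES

__all__ = [
    "delta_hrv",
    "paired_ttest",
    "group_anova",
    "reactivity_summary",
    "PairedTResult",
    "AnovaResult",
]

ALPHA = 0.05


def delta_hrv(
    feature_table: pd.DataFrame, feature_cols: list[str] | None = None
) -> pd.DataFrame:
    """Per-visit within-participant task difference (stress - relaxation).

    Expects a phase- or task-level feature table; visits missing either task
    are skipped with a logged count.  Returns one row per retained
    participant-visit with the per-feature deltas.
    """
    feature_cols = list(feature_cols or FEATURE_NAMES)
    task_col = "task" if "task" in feature_table.columns else "phase"
    df = feature_table[feature_table[task_col].isin(("stress", "relaxation"))]
    wide = df.pivot_table(
        index=["participant", "group", "visit"],
        columns=task_col,
        values=feature_cols,
        aggfunc="first",
        observed=True,
    )
    n_total = len(wide)
    # a visit counts as complete only when both task rows exist
    stress = wide.xs("stress", axis=1, level=1)
    relax = wide.xs("relaxation", axis=1, level=1)
    complete = stress.notna().any(axis=1) & relax.notna().any(axis=1)
    if (~complete).sum():
        warnings.warn(
            f"skipped {int((~complete).sum())} of {n_total} visits missing a task",
            stacklevel=2,
        )
    delta = (stress - relax)[complete]
    out = delta.reset_index()
    out.columns.name = None
    return out


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    degenerate: bool = False


def paired_ttest(stress_values, relax_values) -> PairedTResult:
    """Two-sided paired t-test of stress versus relaxation values.

    Identical pairs give (t=0, p=1).  Constant non-zero differences have no
    within-pair variance and are returned with the ``degenerate`` flag set.
    """
    a = np.asarray(stress_values, dtype=float)
    b = np.asarray(relax_values, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("paired t-test needs >= 2 aligned pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedTResult(0.0, 1.0, degenerate=False)
        return PairedTResult(float("nan"), float("nan"), degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(float(t), float(p), degenerate=False)


@dataclass
class AnovaResult:
    """One-way three-group comparison of one feature's values."""

    feature: str
    f: float
    p: float
    eta_squared: float
    homogeneity_p: float
    route: str  # 'Fisher+Bonferroni' or 'Welch+Games-Howell'
    pairwise: pd.DataFrame = field(repr=False)
    group_means: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _eta_squared(samples: list[np.ndarray]) -> float:
    allv = np.concatenate(samples)
    grand = allv.mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_total = float(np.sum((allv - grand) ** 2))
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def group_anova(
    values, group_labels, feature: str = "", alpha: float = ALPHA
) -> AnovaResult:
    """Homogeneity-gated one-way ANOVA with pairwise post-hocs.

    Brown-Forsythe homogeneity p >= alpha selects Fisher's F with
    Bonferroni-adjusted independent t-tests; otherwise Welch's F with
    Games-Howell.  Eta-squared always comes from the Fisher decomposition.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 3:
        raise InsufficientDataError(f"need 3 groups, got {len(groups)}")
    samples = [values[labels == g] for g in groups]
    if any(s.size < 2 for s in samples):
        raise InsufficientDataError("need >= 2 observations per group")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        # all values identical: no variance anywhere
        hom_p = 1.0
    else:
        _, hom_p = sps.levene(*samples, center="median")
    eta = _eta_squared(samples)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    if hom_p >= alpha:
        route = "Fisher+Bonferroni"
        f, p = sps.f_oneway(*samples)
        if np.isnan(f):  # zero variance everywhere
            f, p = 0.0, 1.0
        for i, j in pairs:
            a, b = samples[i], samples[j]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p_raw = 1.0 if a.mean() == b.mean() else 0.0
            else:
                _, p_raw = sps.ttest_ind(a, b)
            rows.append(
                {
                    "A": groups[i],
                    "B": groups[j],
                    "p": min(1.0, len(pairs) * float(p_raw)),
                    "d": _cohens_d(a, b),
                }
            )
    else:
        route = "Welch+Games-Howell"
        import pingouin as pg

        df = pd.DataFrame({"y": values, "g": labels})
        aov = pg.welch_anova(data=df, dv="y", between="g")
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        f, p = float(aov["F"].iloc[0]), float(aov[p_col].iloc[0])
        gh = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for i, j in pairs:
            ga, gb = groups[i], groups[j]
            row = gh[((gh["A"] == ga) & (gh["B"] == gb)) | ((gh["A"] == gb) & (gh["B"] == ga))]
            rows.append(
                {
                    "A": ga,
                    "B": gb,
                    "p": float(row["pval"].iloc[0]),
                    "d": _cohens_d(samples[i], samples[j]),
                }
            )
    return AnovaResult(
        feature=feature,
        f=float(f),
        p=float(p),
        eta_squared=eta,
        homogeneity_p=float(hom_p),
        route=route,
        pairwise=pd.DataFrame(rows),
        group_means={g: float(s.mean()) for g, s in zip(groups, samples)},
    )


def _direction_label(res: AnovaResult, abs_means: dict) -> str:
    """Rightmost-column rule: list significant pairwise contrasts ordered by
    reactivity magnitude (|group mean delta|); empty when nothing survives
    the post-hoc."""
    parts = []
    for _, row in res.pairwise.iterrows():
        if row["p"] < ALPHA:
            hi, lo = (
                (row["A"], row["B"])
                if abs_means[row["A"]] >= abs_means[row["B"]]
                else (row["B"], row["A"])
            )
            parts.append(f"{hi} > {lo}")
    return "; ".join(parts)


def reactivity_summary(
    delta_records: pd.DataFrame, feature_cols: list[str] | None = None
) -> pd.DataFrame:
    """Group comparison of every feature's delta-HRV.

    One row per feature: per-group mean deltas, the homogeneity-gated ANOVA
    (F, p, eta-squared, route), pairwise post-hoc p-values and Cohen's d,
    and a direction label naming the significant contrasts by reactivity
    magnitude.
    """
    feature_cols = list(feature_cols or FEATURE_NAMES)
    groups = sorted(delta_records["group"].unique().tolist())
    rows = []
    for feat in feature_cols:
        sub = delta_records.dropna(subset=[feat])
        res = group_anova(sub[feat].to_numpy(), sub["group"].to_numpy(), feature=feat)
        row = {
            "feature": feat,
            "F": res.f,
            "p": res.p,
            "eta_squared": res.eta_squared,
            "homogeneity_p": res.homogeneity_p,
            "route": res.route,
        }
        for g in groups:
            row[f"mean_{g}"] = res.group_means.get(g, float("nan"))
        for _, pr in res.pairwise.iterrows():
            tag = f"{pr['A']}-{pr['B']}"
            row[f"p_{tag}"] = pr["p"]
            row[f"d_{tag}"] = pr["d"]
        abs_means = {g: abs(res.group_means[g]) for g in groups}
        row["direction"] = _direction_label(res, abs_means) if res.significant else ""
        rows.append(row)
    return pd.DataFrame(rows)
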