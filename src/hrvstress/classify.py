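"""Subject-wise repeated cross-validated stress/relaxation classification.

The unit of splitting is the participant: all of a participant's rows (both
tasks, all visits) land in the same fold, so no individual ever spans train
and test.  Folds are stratified by diagnostic group; because every
participant-visit contributes one stress and one relaxation row, task
balance inside each fold is structural.

The two classifier families mirror the study design: a random forest tuned
over tree counts {50, 100, 200} and a ReLU multilayer perceptron tuned over
two architectures x three initial learning rates (6 combinations), both via
an inner subject-wise 5-fold grid search on the training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, InsufficientDataError
from .features import FEATURE_NAMES
from .scaling import TrainZScoreScaler, longitudinal_scale
from .treeshap import forest_shap_values

__all__ = [
    "POSITIVE_TASK",
    "TASKS",
    "METRICS",
    "build_labeled_dataset",
    "assign_subject_folds",
    "TunedRandomForest",
    "TunedMLP",
    "make_model",
    "evaluate",
    "undersample",
    "repeated_cv",
    "per_group_models",
    "CVResult",
]

POSITIVE_TASK = "stress"
TASKS = ("stress", "relaxation")
METRICS = ("accuracy", "f1", "recall", "precision", "auc")
SCALING_MODES = ("train-zscore", "longitudinal", "none")


def build_labeled_dataset(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a phase-level feature table to the two task phases.

    Keeps stress and relaxation rows, adds a ``task`` column, and drops rows
    with missing features (logged).  Stress is the positive class.
    """
    df = feature_table[feature_table["phase"].isin(TASKS)].copy()
    df["task"] = df["phase"]
    n0 = len(df)
    df = df.dropna(subset=list(FEATURE_NAMES))
    if len(df) < n0:
        warnings.warn(
            f"dropped {n0 - len(df)} task rows with undefined features",
            stacklevel=2,
        )
    dup = df.duplicated(["participant", "visit", "task"])
    if dup.any():
        raise ConfigError("duplicate (participant, visit, task) rows in dataset")
    return df.reset_index(drop=True)


def assign_subject_folds(
    participants: pd.DataFrame | pd.Series | np.ndarray,
    groups: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict[str, int]:
    """Group-stratified subject-wise fold assignment.

    Accepts either a labeled dataset (DataFrame with ``participant`` and
    ``group`` columns) or parallel participant/group arrays.  Participants
    are shuffled within each diagnostic group and dealt cyclically across
    the ``k`` folds with a running offset, so fold sizes differ by at most
    one overall and per group.  Returns participant -> fold index.
    """
    if isinstance(participants, pd.DataFrame):
        tbl = participants[["participant", "group"]].drop_duplicates("participant")
        pids = tbl["participant"].to_numpy()
        grp = tbl["group"].to_numpy()
    else:
        pids = np.asarray(participants)
        grp = np.asarray(groups) if groups is not None else np.zeros(pids.size, dtype=int)
        order = np.argsort(pids)
        pids, grp = pids[order], grp[order]
        keep = ~pd.Series(pids).duplicated().to_numpy()
        pids, grp = pids[keep], grp[keep]
    if pids.size < k:
        raise ConfigError(f"need >= {k} participants for {k}-fold CV, got {pids.size}")
    rng = np.random.default_rng(seed)
    plan: dict[str, int] = {}
    offset = 0
    for g in sorted(set(grp.tolist())):
        members = pids[grp == g]
        members = members[rng.permutation(members.size)]
        for i, pid in enumerate(members):
            plan[pid] = (offset + i) % k
        offset += members.size
    return plan


def _inner_subject_folds(pids: np.ndarray, k: int, rng: np.random.Generator) -> dict:
    uniq = np.unique(pids)
    uniq = uniq[rng.permutation(uniq.size)]
    return {pid: i % k for i, pid in enumerate(uniq)}


class _SubjectWiseGridSearch(ClassifierMixin, BaseEstimator):
    """Grid search with a subject-wise inner CV, refit on all training rows.

    Subclasses define ``_grid()`` (candidates in preference order: on ties
    the earliest wins) and ``_build(candidate)``.  ``fit`` requires a
    ``groups`` vector of participant ids aligned with the rows.
    """

    def __init__(self, inner_cv: int = 5, random_state: int = 0):
        self.inner_cv = inner_cv
        self.random_state = random_state

    def _grid(self) -> list:
        raise NotImplementedError

    def _build(self, candidate) -> BaseEstimator:
        raise NotImplementedError

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise InsufficientDataError("training set contains a single class")
        if groups is None:
            groups = np.arange(len(y))  # degenerate: row-wise folds
        groups = np.asarray(groups)
        rng = np.random.default_rng(self.random_state)
        k = min(self.inner_cv, np.unique(groups).size)
        plan = _inner_subject_folds(groups, k, rng)
        fold_of = np.vectorize(plan.get)(groups)
        scores = []
        for cand in self._grid():
            accs = []
            for f in range(k):
                tr, te = fold_of != f, fold_of == f
                if np.unique(y[tr]).size < 2 or te.sum() == 0:
                    continue
                est = self._build(cand).fit(X[tr], y[tr])
                accs.append(accuracy_score(y[te], est.predict(X[te])))
            scores.append(np.mean(accs) if accs else -np.inf)
        best_idx = int(np.argmax(scores))  # argmax keeps the first on ties
        self.best_params_ = self._grid()[best_idx]
        self.cv_scores_ = np.asarray(scores)
        self.best_estimator_ = self._build(self.best_params_).fit(X, y)
        self.classes_ = self.best_estimator_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(X)


class TunedRandomForest(_SubjectWiseGridSearch):
    """Random forest with the tree count tuned over {50, 100, 200}.

    Ties prefer the smallest forest.  Non-grid hyperparameters are the
    library defaults (Gini impurity, sqrt(p) features per split, unlimited
    depth).
    """

    def __init__(self, n_estimators_grid=(50, 100, 200), inner_cv=5, random_state=0):
        super().__init__(inner_cv=inner_cv, random_state=random_state)
        self.n_estimators_grid = n_estimators_grid

    def _grid(self):
        return sorted(self.n_estimators_grid)

    def _build(self, candidate):
        return RandomForestClassifier(
            n_estimators=int(candidate), random_state=self.random_state, n_jobs=1
        )

    def fit(self, X, y, groups=None):
        # Warm-start fast path: growing one forest 50 -> 100 -> 200 per inner
        # fold yields tree-for-tree the same ensembles as independent fits
        # with the same random_state (sklearn draws per-tree seeds from one
        # stream), so scores, tie-breaks and the refit model are identical
        # to the generic grid-search path.
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise InsufficientDataError("training set contains a single class")
        if groups is None:
            groups = np.arange(len(y))
        groups = np.asarray(groups)
        rng = np.random.default_rng(self.random_state)
        k = min(self.inner_cv, np.unique(groups).size)
        plan = _inner_subject_folds(groups, k, rng)
        fold_of = np.vectorize(plan.get)(groups)
        grid = self._grid()
        accs = {n: [] for n in grid}
        for f in range(k):
            tr, te = fold_of != f, fold_of == f
            if np.unique(y[tr]).size < 2 or te.sum() == 0:
                continue
            forest = RandomForestClassifier(
                n_estimators=grid[0], random_state=self.random_state,
                n_jobs=1, warm_start=True,
            )
            for n in grid:
                forest.set_params(n_estimators=int(n))
                forest.fit(X[tr], y[tr])
                accs[n].append(accuracy_score(y[te], forest.predict(X[te])))
        scores = [np.mean(accs[n]) if accs[n] else -np.inf for n in grid]
        best_idx = int(np.argmax(scores))
        self.best_params_ = grid[best_idx]
        self.cv_scores_ = np.asarray(scores)
        self.best_estimator_ = self._build(self.best_params_).fit(X, y)
        self.classes_ = self.best_estimator_.classes_
        return self


class TunedMLP(_SubjectWiseGridSearch):
    """ReLU multilayer perceptron tuned over architecture x learning rate.

    The grid is {(4, 8, 16), (4, 8, 16, 32)} x {1e-4, 1e-3, 1e-2} — six
    combinations.  Dense ReLU hidden layers, logistic output, Adam solver,
    L2 coefficient 1e-4, at most 1000 iterations, early stopping when the
    validation score improves by < 1e-4 for 10 consecutive iterations.
    Ties prefer the smaller architecture, then the smaller learning rate.
    Non-convergence is logged as a warning and the best-so-far model kept.
    """

    def __init__(
        self,
        architectures=((4, 8, 16), (4, 8, 16, 32)),
        learning_rates=(1e-4, 1e-3, 1e-2),
        inner_cv=5,
        random_state=0,
    ):
        super().__init__(inner_cv=inner_cv, random_state=random_state)
        self.architectures = architectures
        self.learning_rates = learning_rates

    def _grid(self):
        return [
            (arch, lr)
            for arch in sorted(self.architectures, key=len)
            for lr in sorted(self.learning_rates)
        ]

    def _build(self, candidate):
        arch, lr = candidate
        return _WarnOnceMLP(
            hidden_layer_sizes=tuple(arch),
            activation="relu",
            solver="adam",
            alpha=1e-4,
            learning_rate_init=float(lr),
            max_iter=1000,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=10,
            tol=1e-4,
            random_state=self.random_state,
        )


class _WarnOnceMLP(MLPClassifier):
    """MLP that demotes sklearn's convergence error chatter to a single log
    warning (the best-so-far model is returned either way)."""

    def fit(self, X, y):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            super().fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            warnings.warn(
                "MLP did not fully converge within max_iter; "
                "returning best-so-far model",
                stacklevel=2,
            )
        return self


def make_model(family: str, seed: int = 0, **kwargs) -> _SubjectWiseGridSearch:
    """Instantiate a tuned classifier by family name ('rf' or 'mlp')."""
    if family in ("rf", "random_forest"):
        return TunedRandomForest(random_state=seed, **kwargs)
    if family == "mlp":
        return TunedMLP(random_state=seed, **kwargs)
    raise ConfigError(f"unknown model family {family!r}; expected 'rf' or 'mlp'")


def evaluate(
    proba: np.ndarray,
    pred: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, dict[str, float]]:
    """Classification metrics on the positive (stress) class.

    Returns ``{scope: {metric: value}}`` with scope 'overall' plus each
    diagnostic group present.  AUC is NaN for a scope whose test rows carry
    a single class.
    """
    proba = np.asarray(proba, dtype=float)
    pred = np.asarray(pred)
    labels = np.asarray(labels)

    def _metrics(mask: np.ndarray) -> dict[str, float]:
        yt, yp, pr = labels[mask], pred[mask], proba[mask]
        out = {
            "accuracy": accuracy_score(yt, yp),
            "f1": f1_score(yt, yp, zero_division=0),
            "recall": recall_score(yt, yp, zero_division=0),
            "precision": precision_score(yt, yp, zero_division=0),
        }
        out["auc"] = (
            roc_auc_score(yt, pr) if np.unique(yt).size > 1 else float("nan")
        )
        return {k: float(v) for k, v in out.items()}

    scopes = {"overall": np.ones(labels.size, dtype=bool)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in sorted(set(groups.tolist())):
            scopes[g] = groups == g
    return {s: _metrics(m) for s, m in scopes.items() if m.any()}


def undersample(dataset: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Random undersampling to the smallest group's sample size.

    Sampling operates on participant-visit sessions (so stress/relaxation
    pairing is preserved) and is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    sessions = dataset[["participant", "group", "visit"]].drop_duplicates(
        ["participant", "visit"]
    )
    n_min = sessions.groupby("group").size().min()
    keep_keys = []
    for g, sub in sessions.groupby("group", sort=True):
        idx = rng.choice(len(sub), size=int(n_min), replace=False)
        keep_keys.append(sub.iloc[np.sort(idx)][["participant", "visit"]])
    keep = pd.concat(keep_keys)
    out = dataset.merge(keep, on=["participant", "visit"], how="inner")
    return out.reset_index(drop=True)


@dataclass
class CVResult:
    """Repeated-CV outcome: per-repeat metrics and their mean/SD summary.

    ``per_repeat`` has one row per (repeat, scope); ``shap_abs`` (present
    when attributions were collected) has one row per (repeat, scope) and
    one column per feature holding the repeat-level mean |Shapley value|.
    """

    per_repeat: pd.DataFrame
    model_family: str
    scaling_mode: str
    scope_label: str = "combined"
    shap_abs: pd.DataFrame | None = None
    warnings_: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and SD over repeats for each scope x metric (study report shape)."""
        rows = []
        for scope, sub in self.per_repeat.groupby("scope", sort=False):
            for m in METRICS:
                rows.append(
                    {
                        "scope": scope,
                        "metric": m,
                        "mean": float(np.nanmean(sub[m])),
                        "sd": float(np.nanstd(sub[m], ddof=1)) if len(sub) > 1 else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def metric(self, metric: str, scope: str = "overall") -> float:
        s = self.summary()
        row = s[(s["scope"] == scope) & (s["metric"] == metric)]
        if row.empty:
            raise KeyError(f"no scope {scope!r} / metric {metric!r}")
        return float(row["mean"].iloc[0])


def repeated_cv(
    dataset: pd.DataFrame,
    model: str = "rf",
    k: int = 10,
    repeats: int = 20,
    scaling_mode: str = "train-zscore",
    base_seed: int = 0,
    collect_shap: bool = False,
    scope_label: str = "combined",
) -> CVResult:
    """Subject-wise k-fold CV repeated ``repeats`` times.

    Per repeat: a fresh group-stratified fold plan (seed = base_seed +
    repeat), one tuned model per fold, metrics averaged over folds (overall
    and per diagnostic group).  The summary reports mean +/- SD over the
    repeat-level values.

    ``scaling_mode``:
      * 'train-zscore'  — z-scaling fit inside each training fold;
      * 'longitudinal'  — personalized longitudinal scaling applied to the
        whole table up front (no fold-level scaling);
      * 'none'          — raw features.

    With ``collect_shap=True`` (random forest only) exact tree Shapley
    attributions are computed on every test fold and summarised per repeat.
    """
    if scaling_mode not in SCALING_MODES:
        raise ConfigError(
            f"scaling_mode {scaling_mode!r} not in {SCALING_MODES}"
        )
    df = dataset.copy()
    if scaling_mode == "longitudinal":
        df = longitudinal_scale(df)
    feature_cols = list(FEATURE_NAMES)
    y_all = (df["task"] == POSITIVE_TASK).to_numpy(dtype=int)
    pid_all = df["participant"].to_numpy()
    grp_all = df["group"].to_numpy()
    X_all = df[feature_cols].to_numpy(dtype=float)

    repeat_rows = []
    shap_rows = []
    for rep in range(repeats):
        plan = assign_subject_folds(df, k=k, seed=base_seed + rep)
        fold_of = np.vectorize(plan.get)(pid_all)
        fold_metrics: dict[str, list[dict[str, float]]] = {}
        abs_shap_sum: dict[str, np.ndarray] = {}
        abs_shap_n: dict[str, int] = {}
        for f in range(k):
            te = fold_of == f
            tr = ~te
            train_pids = set(pid_all[tr])
            test_pids = set(pid_all[te])
            if train_pids & test_pids:  # leakage guard
                raise AssertionError(
                    f"participant leakage between train and test in fold {f}: "
                    f"{sorted(train_pids & test_pids)[:3]}"
                )
            Xtr, Xte = X_all[tr], X_all[te]
            if scaling_mode == "train-zscore":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scaler = TrainZScoreScaler(provenance=f"rep{rep}-fold{f}").fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            seed = (base_seed * 100_003 + rep * 1009 + f) % (2**31 - 1)
            est = make_model(model, seed=seed)
            est.fit(Xtr, y_all[tr], groups=pid_all[tr])
            proba = est.predict_proba(Xte)[:, list(est.classes_).index(1)]
            pred = est.predict(Xte)
            sc = evaluate(proba, pred, y_all[te], grp_all[te])
            for scope, m in sc.items():
                fold_metrics.setdefault(scope, []).append(m)
            if collect_shap:
                phi, _ = forest_shap_values(est.best_estimator_, Xte)
                for scope, mask in _scope_masks(grp_all[te]).items():
                    if not mask.any():
                        continue
                    s = np.abs(phi[mask]).sum(axis=0)
                    abs_shap_sum[scope] = abs_shap_sum.get(scope, 0.0) + s
                    abs_shap_n[scope] = abs_shap_n.get(scope, 0) + int(mask.sum())
        for scope, ms in fold_metrics.items():
            row = {"repeat": rep, "scope": scope}
            for metric in METRICS:
                vals = np.asarray([m[metric] for m in ms], dtype=float)
                row[metric] = float(np.nanmean(vals))
            repeat_rows.append(row)
        for scope, s in abs_shap_sum.items():
            row = {"repeat": rep, "scope": scope}
            row.update(dict(zip(feature_cols, s / abs_shap_n[scope])))
            shap_rows.append(row)
    return CVResult(
        per_repeat=pd.DataFrame(repeat_rows),
        model_family=model,
        scaling_mode=scaling_mode,
        scope_label=scope_label,
        shap_abs=pd.DataFrame(shap_rows) if shap_rows else None,
    )


def _scope_masks(groups: np.ndarray) -> dict[str, np.ndarray]:
    out = {"overall": np.ones(groups.size, dtype=bool)}
    for g in sorted(set(groups.tolist())):
        out[g] = groups == g
    return out


def per_group_models(
    dataset: pd.DataFrame,
    model: str = "rf",
    k: int = 10,
    repeats: int = 20,
    scaling_mode: str = "train-zscore",
    base_seed: int = 0,
    collect_shap: bool = False,
) -> dict[str, CVResult]:
    """Train and evaluate one model per diagnostic group, on that group's
    data exclusively."""
    out = {}
    for g, sub in dataset.groupby("group", sort=True):
        out[g] = repeated_cv(
            sub.reset_index(drop=True),
            model=model,
            k=k,
            repeats=repeats,
            scaling_mode=scaling_mode,
            base_seed=base_seed,
            collect_shap=collect_shap,
            scope_label=str(g),
        )
    return out
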