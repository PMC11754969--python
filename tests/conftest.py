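"""Shared fixtures: small synthetic cohorts and their feature tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

import hrvstress as hs


@pytest.fixture(scope="session")
def small_cohort():
    """2/2/2 participants, 2 visits, all phases retained."""
    cfg = hs.CohortConfig(
        n_per_group={"MDD": 2, "PD": 2, "HC": 2},
        n_visits=2,
        retention_prob=1.0,
        seed=3,
    )
    return cfg, hs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, cohort = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hs.extract_cohort_features(cohort)


def drift_dominated_config(seed: int) -> hs.CohortConfig:
    """Study conditions for the personalization experiments: healthy
    controls react roughly twice as strongly as patients, and day-to-day
    baseline drift plus between-subject heterogeneity dwarf the task
    effect."""
    return hs.CohortConfig(
        n_per_group={"MDD": 6, "PD": 6, "HC": 6},
        n_visits=2,
        visit_drift_sd=80.0,
        subject_sd=80.0,
        amp_subject_sd=0.35,
        reactivity_subject_sd=0.25,
        retention_prob=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def drift_features():
    """Feature table of the seed-0 drift-dominated cohort (shared by the
    scaling-QA and classification-ordering tests to amortise extraction)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hs.extract_cohort_features(hs.generate_cohort(drift_dominated_config(0)))


def make_labeled_frame(
    n_per_group=(4, 4, 4),
    n_visits=2,
    effect=2.0,
    noise=0.5,
    seed=0,
) -> pd.DataFrame:
    """Hand-built labeled dataset (no simulator): a planted task signal on
    ``mean_rri`` plus white noise on every feature.  Fast scaffolding for
    classifier plumbing tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in zip(hs.GROUPS, n_per_group):
        for i in range(n):
            pid = f"{g}{i:02d}"
            for v in range(1, n_visits + 1):
                for task in ("stress", "relaxation"):
                    feats = rng.normal(0.0, noise, size=len(hs.FEATURE_NAMES))
                    if task == "stress":
                        feats[0] += effect
                    rows.append(
                        dict(
                            zip(hs.FEATURE_NAMES, feats),
                            participant=pid,
                            group=g,
                            visit=v,
                            phase=task,
                            task=task,
                        )
                    )
    return pd.DataFrame(rows)
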