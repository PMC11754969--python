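"""Table formats, configuration, run manifest, and end-to-end orchestration.

The interchange format for raw data is a long-format CSV with columns
``participant,group,visit,phase,beat_index,rri_ms`` (gzip transparently
supported via the ``.gz`` suffix).  Every pipeline run writes a JSON
manifest capturing the configuration snapshot, seeds, package version,
SHA-256 digests of each stage's outputs and the warnings raised, so any
output can be traced to the run that produced it and reruns are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    GROUPS,
    PHASES,
    CohortConfig,
    GroupEffect,
    Reactivity,
    RRISeries,
    generate_cohort,
)
from .classify import build_labeled_dataset, per_group_models, repeated_cv, undersample
from .errors import ConfigError, ParseError
from .features import FEATURE_NAMES, extract_cohort_features
from .interpret import importance_report
from .scaling import longitudinal_scale
from .stats import delta_hrv, reactivity_summary

__all__ = [
    "read_rri_table",
    "read_rri_text",
    "write_rri_table",
    "load_cohort_config",
    "RunManifest",
    "run_pipeline",
]

_RRI_COLUMNS = ["participant", "group", "visit", "phase", "beat_index", "rri_ms"]


def write_rri_table(cohort, path) -> None:
    """Write a cohort as long-format CSV (one row per beat)."""
    frames = []
    for s in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "participant": s.participant_id,
                    "group": s.group,
                    "visit": s.visit,
                    "phase": s.phase,
                    "beat_index": np.arange(s.n_beats),
                    "rri_ms": s.intervals_ms,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rri_table(path) -> list[RRISeries]:
    """Read a long-format RRI CSV into a cohort of validated series.

    Group and phase tokens must be known, intervals positive, and
    ``beat_index`` contiguous from 0 within each (participant, visit,
    phase); violations raise :class:`ParseError` naming the offending row.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty cohort")
    missing = set(_RRI_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        row = int(df.index[bad_group][0])
        raise ParseError(
            f"{path}: unknown group {df['group'].iloc[row]!r} at row {row + 2}"
        )
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        row = int(df.index[bad_phase][0])
        raise ParseError(
            f"{path}: unknown phase {df['phase'].iloc[row]!r} at row {row + 2}"
        )
    nonpos = df["rri_ms"] <= 0
    if nonpos.any():
        row = int(df.index[nonpos][0])
        raise ParseError(
            f"{path}: non-positive interval {df['rri_ms'].iloc[row]} at row {row + 2}"
        )
    cohort = []
    for (pid, group, visit, phase), sub in df.groupby(
        ["participant", "group", "visit", "phase"], sort=True
    ):
        bi = sub["beat_index"].to_numpy()
        if not np.array_equal(bi, np.arange(bi.size)):
            first_bad = int(sub.index[0])
            raise ParseError(
                f"{path}: beat_index not contiguous from 0 for "
                f"({pid}, visit {visit}, {phase}) starting at row {first_bad + 2}"
            )
        cohort.append(
            RRISeries(str(pid), str(group), int(visit), str(phase),
                      sub["rri_ms"].to_numpy(dtype=float))
        )
    return cohort


def read_rri_text(
    path, participant: str, group: str, visit: int, phase: str
) -> RRISeries:
    """Read a one-interval-per-line plain-text series (ms) with its
    metadata supplied as arguments (sidecar style)."""
    if group not in GROUPS:
        raise ParseError(f"unknown group {group!r}")
    if phase not in PHASES:
        raise ParseError(f"unknown phase {phase!r}")
    vals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            v = float(line)
            if v <= 0:
                raise ParseError(f"{path}: non-positive interval {v} at line {i}")
            vals.append(v)
    if not vals:
        raise ParseError(f"{path}: empty series")
    return RRISeries(participant, group, int(visit), phase, np.asarray(vals))


def load_cohort_config(source) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML/JSON file path or a dict."""
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("cohort config must be a mapping")
    if "group_offsets" in data:
        data["group_offsets"] = {
            g: GroupEffect(**v) if isinstance(v, dict) else v
            for g, v in data["group_offsets"].items()
        }
    if "reactivity" in data:
        data["reactivity"] = {
            g: Reactivity(**v) if isinstance(v, dict) else v
            for g, v in data["reactivity"].items()
        }
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    cfg = CohortConfig(**data)
    cfg.validate()
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)

    def record(self, stage: str, path: Path) -> None:
        self.outputs[stage] = {"path": str(path), "sha256": _digest(path)}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


_DEFAULT_PIPELINE = {
    "scaling": "train-zscore",  # or 'longitudinal' or 'none'
    "model": "rf",
    "repeats": 20,
    "k": 10,
    "undersample": False,
    "per_group": False,
    "shap": True,
    "stats": True,
    "seed": 0,
}


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Run the full analysis: simulate/ingest -> correct+extract -> scale ->
    classify (+ attribution) -> delta-HRV statistics.

    ``config`` keys: either ``cohort`` (a :class:`CohortConfig` mapping) or
    ``rri_path`` (an RRI CSV); plus any of ``scaling``, ``model``,
    ``repeats``, ``k``, ``undersample``, ``per_group``, ``shap``, ``stats``,
    ``seed``.  All stage outputs plus a ``manifest.json`` land in
    ``out_dir``; rerunning the same config reproduces identical outputs.
    """
    opts = dict(_DEFAULT_PIPELINE)
    unknown = set(config) - set(opts) - {"cohort", "rri_path"}
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    opts.update(config)
    scaling = opts["scaling"]
    if isinstance(scaling, (list, tuple, set)):
        if len(set(scaling)) > 1:
            raise ConfigError(
                "train-zscore and longitudinal scaling are mutually exclusive; "
                "request exactly one scaling regime"
            )
        scaling = next(iter(scaling))
    if scaling not in ("train-zscore", "longitudinal", "none"):
        raise ConfigError(f"unknown scaling regime {scaling!r}")
    if ("cohort" in config) == ("rri_path" in config):
        raise ConfigError("config needs exactly one of 'cohort' or 'rri_path'")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(opts["seed"])
    snapshot = {k: v for k, v in opts.items()}
    manifest = RunManifest(config=_jsonable(snapshot | dict(config)), seed=seed)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # stage 1: cohort
        if "cohort" in config:
            cfg = load_cohort_config(config["cohort"])
            cohort = generate_cohort(cfg)
            rri_path = out / "rri.csv"
            write_rri_table(cohort, rri_path)
            manifest.record("simulate", rri_path)
        else:
            cohort = read_rri_table(config["rri_path"])

        # stage 2: artifact correction + feature extraction
        features = extract_cohort_features(cohort, correct=True)
        feat_path = out / "features.csv"
        features.to_csv(feat_path, index=False)
        manifest.record("extract", feat_path)

        # stage 3: scaling (longitudinal is applied to the full phase table,
        # using every phase of every visit; train-zscore happens inside CV)
        if scaling == "longitudinal":
            scaled = longitudinal_scale(features)
            scaled_path = out / "features_scaled.csv"
            scaled.to_csv(scaled_path, index=False)
            manifest.record("scale", scaled_path)
            dataset = build_labeled_dataset(scaled)
            cv_mode = "none"
        else:
            dataset = build_labeled_dataset(features)
            cv_mode = scaling

        if opts["undersample"]:
            dataset = undersample(dataset, seed=seed)

        # stage 4: classification
        cv = repeated_cv(
            dataset,
            model=opts["model"],
            k=int(opts["k"]),
            repeats=int(opts["repeats"]),
            scaling_mode=cv_mode,
            base_seed=seed,
            collect_shap=bool(opts["shap"]) and opts["model"] in ("rf", "random_forest"),
        )
        metrics_path = out / "metrics.json"
        _write_metrics(cv, metrics_path)
        manifest.record("classify", metrics_path)

        if opts["per_group"]:
            pg = per_group_models(
                dataset, model=opts["model"], k=int(opts["k"]),
                repeats=int(opts["repeats"]), scaling_mode=cv_mode, base_seed=seed,
            )
            pg_path = out / "metrics_per_group.json"
            pg_path.write_text(
                json.dumps(
                    {g: _metrics_dict(r) for g, r in pg.items()},
                    indent=2, sort_keys=True,
                )
            )
            manifest.record("per_group", pg_path)

        # stage 5: attribution
        if cv.shap_abs is not None:
            report = importance_report(cv, regime=scaling)
            imp_path = out / "importance.csv"
            report.to_csv(imp_path, index=False)
            manifest.record("interpret", imp_path)

        # stage 6: delta-HRV statistics (on the same regime the models saw)
        if opts["stats"]:
            delta_source = scaled if scaling == "longitudinal" else features
            deltas = delta_hrv(delta_source)
            summary = reactivity_summary(deltas)
            stats_path = out / "delta_stats.csv"
            summary.to_csv(stats_path, index=False)
            manifest.record("stats", stats_path)

    manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.write(out / "manifest.json")
    return manifest


def _metrics_dict(cv) -> dict:
    s = cv.summary()
    out: dict = {}
    for scope, sub in s.groupby("scope", sort=True):
        out[scope] = {
            row["metric"]: {"mean": round(row["mean"], 10), "sd": round(row["sd"], 10)}
            for _, row in sub.iterrows()
        }
    return out


def _write_metrics(cv, path: Path) -> None:
    path.write_text(json.dumps(_metrics_dict(cv), indent=2, sort_keys=True))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
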