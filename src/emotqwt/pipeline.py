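"""End-to-end experiment orchestration.

Four run modes tie the stages together (decompose -> features -> optional
BGWO selection -> SVM CV):

- ``per_subject``: each subject's sub-band-fused matrices classified
  before and after selection, per feature type;
- ``per_subband``: all subjects fused, one matrix per (sub-band, feature
  type), before/after selection accuracy;
- ``all_fused``: subjects and sub-bands fused, full Acc/Sen/Spe/Kappa per
  feature type;
- ``param_sweep``: per-subject grid over (Q, J) at fixed r, reporting each
  subject's best setting (ties broken by smaller J, then smaller Q).

Every report embeds the configuration and seeds so any number in it can be
recomputed; per-stage wall-clock durations are recorded for information
only.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import svm_cv
from .features import FEATURE_TYPES, FeatureMatrix, extract_features, fuse
from .io import EEGRecording, RatingRecord, load_recording
from .preprocess import preprocess_recording, ratings_to_classes
from .selection import bgwo_select
from .tqwt import TQWTParams, max_stages

__all__ = ["RunConfig", "run_mode", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML-serializable)."""

    mode: str = "per_subject"
    Q: float = 3.0
    r: float = 3.0
    J: int = 4
    q_grid: tuple = (1, 2, 3, 4, 5)
    j_grid: tuple = (1, 2, 3, 4, 5, 6)
    features: tuple = FEATURE_TYPES
    selection: bool = True
    pack_size: int = 8
    n_iter: int = 70
    w: float = 0.99
    cv_folds: int = 6
    seed: int = 0
    preprocess: bool = True
    circumplex: bool = False
    inputs: tuple = ()      # DEAP-layout file paths (unused if cohort given)
    out_dir: str | None = None


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    for key in ("q_grid", "j_grid", "features", "inputs"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _load_cohort(config: RunConfig):
    recordings, ratings = [], []
    for path in config.inputs:
        rec, rr = load_recording(path)
        recordings.append(rec)
        ratings.append(rr)
    return recordings, ratings


def _prepare(config: RunConfig, recordings, ratings):
    if config.preprocess:
        recordings = [preprocess_recording(r) for r in recordings]
    labels = [ratings_to_classes(rr, circumplex=config.circumplex) for rr in ratings]
    return recordings, labels


def _before_after(
    mat: FeatureMatrix, y: np.ndarray, config: RunConfig
) -> dict:
    """CV accuracy on all columns, then on the BGWO-selected columns."""
    before = svm_cv(mat.values, y, k_folds=config.cv_folds, seed=config.seed)
    entry = {
        "before_acc": before.acc,
        "n_columns": mat.shape[1],
    }
    if config.selection:
        sel = bgwo_select(
            mat.values,
            y,
            pack_size=config.pack_size,
            T=config.n_iter,
            seed=config.seed,
            fitness_kwargs={"folds": config.cv_folds, "w": config.w},
        )
        keep = sel.mask.astype(bool)
        after = svm_cv(mat.values[:, keep], y, k_folds=config.cv_folds,
                       seed=config.seed)
        entry.update(
            after_acc=after.acc,
            n_selected=sel.n_selected,
            best_fitness=sel.best_fitness,
        )
    return entry


def run_mode(
    config: RunConfig,
    recordings: list[EEGRecording] | None = None,
    ratings: list[list[RatingRecord]] | None = None,
) -> dict:
    """Execute one experiment mode; returns (and optionally writes) the
    report bundle as a plain dict."""
    t0 = time.perf_counter()
    if recordings is None:
        recordings, ratings = _load_cohort(config)
    if not recordings:
        raise ValueError("no input recordings")
    recordings, labels = _prepare(config, recordings, ratings)
    timings = {"prepare": time.perf_counter() - t0}

    report: dict = {"mode": config.mode, "config": asdict(config)}
    t0 = time.perf_counter()

    if config.mode == "per_subject":
        report["subjects"] = {}
        params = TQWTParams(config.Q, config.r, config.J)
        for rec, y in zip(recordings, labels):
            mats = extract_features(rec, params, features=config.features)
            report["subjects"][rec.subject_id] = {
                f: _before_after(mats[f], y, config) for f in config.features
            }

    elif config.mode == "per_subband":
        params = TQWTParams(config.Q, config.r, config.J)
        per_subject = [
            extract_features(rec, params, features=config.features)
            for rec in recordings
        ]
        y_all = np.concatenate(labels)
        report["subbands"] = {}
        for sb in range(1, config.J + 2):
            report["subbands"][f"SB{sb}"] = {}
            for f in config.features:
                mat = fuse([m[f] for m in per_subject],
                           "per_subband_subject_fused", subband=sb)
                report["subbands"][f"SB{sb}"][f] = _before_after(mat, y_all, config)

    elif config.mode == "all_fused":
        params = TQWTParams(config.Q, config.r, config.J)
        per_subject = [
            extract_features(rec, params, features=config.features)
            for rec in recordings
        ]
        y_all = np.concatenate(labels)
        report["features"] = {}
        for f in config.features:
            mat = fuse([m[f] for m in per_subject], "all_fused")
            before = svm_cv(mat.values, y_all, k_folds=config.cv_folds,
                            seed=config.seed)
            entry = {"before_acc": before.acc, "n_columns": mat.shape[1]}
            final = mat.values
            if config.selection:
                sel = bgwo_select(
                    mat.values, y_all, pack_size=config.pack_size,
                    T=config.n_iter, seed=config.seed,
                    fitness_kwargs={"folds": config.cv_folds, "w": config.w},
                )
                final = mat.values[:, sel.mask.astype(bool)]
                entry.update(n_selected=sel.n_selected,
                             best_fitness=sel.best_fitness)
            # full four-index report on the final (possibly selected) matrix
            cv = svm_cv(final, y_all, k_folds=config.cv_folds, seed=config.seed)
            entry.update(acc=cv.acc, sen=cv.sen, spe=cv.spe, kappa=cv.kappa,
                         after_acc=cv.acc if config.selection else None)
            report["features"][f] = entry

    elif config.mode == "param_sweep":
        report["subjects"] = {}
        for rec, y in zip(recordings, labels):
            cells = []
            for Q in config.q_grid:
                for J in config.j_grid:
                    params = TQWTParams(Q, config.r, J)
                    if J > max_stages(params, rec.n_samples):
                        cells.append(
                            {"Q": Q, "J": J, "skipped": "J exceeds max_stages"}
                        )
                        continue
                    mats = extract_features(rec, params, features=config.features)
                    fused = np.hstack([mats[f].values for f in config.features])
                    mat = FeatureMatrix(
                        fused,
                        "fused",
                        [(i, f"c{i}") for i in range(fused.shape[1])],
                        mats[config.features[0]].row_index,
                    )
                    cell = _before_after(mat, y, config)
                    cell.update(Q=Q, J=J)
                    cells.append(cell)
            key = "after_acc" if config.selection else "before_acc"
            scored = [c for c in cells if "skipped" not in c]
            best = max(scored, key=lambda c: (c[key], -c["J"], -c["Q"]))
            report["subjects"][rec.subject_id] = {"cells": cells, "best": best}
        key = "after_acc" if config.selection else "before_acc"
        report["summary"] = {
            "mean_best_acc": float(
                np.mean([s["best"][key] for s in report["subjects"].values()])
            )
        }
    else:
        raise ValueError(f"unknown mode: {config.mode}")

    timings[config.mode] = time.perf_counter() - t0
    report["timings_s"] = timings

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"report_{config.mode}.json", "w") as f:
            json.dump(report, f, indent=2, default=_json_default)
        _flat_csv(report, out / f"report_{config.mode}.csv")
    return report


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _flat_csv(report: dict, path: Path) -> None:
    rows = []
    if "subjects" in report:
        for subj, entry in report["subjects"].items():
            if "cells" in entry:  # param sweep
                for cell in entry["cells"]:
                    rows.append({"subject": subj, **cell})
            else:
                for f, metrics in entry.items():
                    rows.append({"subject": subj, "feature": f, **metrics})
    elif "subbands" in report:
        for sb, entry in report["subbands"].items():
            for f, metrics in entry.items():
                rows.append({"subband": sb, "feature": f, **metrics})
    elif "features" in report:
        for f, metrics in report["features"].items():
            rows.append({"feature": f, **metrics})
    if rows:
        pd.DataFrame(rows).to_csv(path, index=False)
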