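"""Experiment orchestration: subject splits, configuration, end-to-end runs.

An experiment goes: synthetic cohort -> connectivity features ->
parcellation -> (optional hyperparameter tuning) -> per-task, per-model
ensemble training -> prediction on held-out test subjects -> evaluation
(correlation matrices, accuracy, mixture-threshold Dice, repeated-measures
ANOVA, learning/averaging curves).  A single master seed derives every
stage seed through a stable hash, so any stage can be reproduced in
isolation and a re-run of the same configuration is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import evaluation as ev
from .features import extract_cohort_features
from .models import predict_ensemble, train_ensemble
from .tuning import NN_DEFAULTS, RFBAG_DEFAULTS, tune_nn, tune_rfbag

__all__ = [
    "SplitSpec",
    "ExperimentConfig",
    "derive_seed",
    "make_split",
    "run_experiment",
]

log = logging.getLogger("resttask")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256 of (master seed, stage name) mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SplitSpec:
    """Disjoint training / test / hyperparameter-optimisation subject sets."""

    train_ids: list[str]
    test_ids: list[str]
    hyperopt_ids: list[str]
    inner_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    master_seed: int = 0

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.test_ids), set(self.hyperopt_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/test/hyperopt subject sets must be disjoint")
        if abs(sum(self.inner_fractions) - 1.0) > 1e-9:
            raise ValueError("inner split fractions must sum to 1")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def load(cls, path: str | Path) -> "SplitSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["inner_fractions"] = tuple(d["inner_fractions"])
        return cls(**d)


def make_split(
    subject_ids: list[str], counts: tuple[int, int, int], seed: int = 0
) -> SplitSpec:
    """Seeded random assignment into (train, test, hyperopt) sets."""
    n_train, n_test, n_hyper = counts
    if n_train + n_test + n_hyper > len(subject_ids):
        raise ValueError(
            f"requested {n_train + n_test + n_hyper} subjects, only {len(subject_ids)} available"
        )
    rng = np.random.default_rng(seed)
    order = [subject_ids[i] for i in rng.permutation(len(subject_ids))]
    return SplitSpec(
        train_ids=sorted(order[:n_train]),
        test_ids=sorted(order[n_train : n_train + n_test]),
        hyperopt_ids=sorted(order[n_train + n_test : n_train + n_test + n_hyper]),
        master_seed=seed,
    )


@dataclass
class ExperimentConfig:
    """Full description of one synthetic-cohort experiment."""

    cohort: dict = field(default_factory=dict)  # kwargs for make_cohort
    split_counts: tuple[int, int, int] = (40, 10, 10)
    model_kinds: tuple[str, ...] = ("glm", "nn", "rfbag")
    hyperparams: dict = field(default_factory=dict)  # kind -> dict
    tune: bool = False
    tuning_grids: dict = field(default_factory=dict)  # kind -> grids
    m_averages: int = 1
    n_train_grid: tuple[int, ...] = ()
    m_grid: tuple[int, ...] = ()
    feature_source: str = "estimated"  # "estimated" | "true"
    target_dim: int = 100
    k_ica: int = 12
    symmetry_threshold: float = 0.5
    master_seed: int = 0
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("split_counts", "model_kinds", "n_train_grid", "m_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline described by ``config``.

    Returns a report dict with, per task and model, the raw and normalised
    correlation matrices, mean diagonal accuracy, mean Dice, the
    cross-model ANOVA, and optional learning/averaging curves.  Artifacts
    (report CSV, config, split) are written to ``config.out_dir`` when
    set; every artifact records the config hash so a run can be replayed
    exactly.
    """
    timings: dict[str, float] = {}
    chash = config.config_hash()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")

    t0 = _stage("cohort")
    cohort_kwargs = dict(config.cohort)
    cohort_kwargs.setdefault("seed", derive_seed(config.master_seed, "cohort"))
    subjects, truth, space, parc = cohort_mod.make_cohort(**cohort_kwargs)
    by_id = {s.subject_id: s for s in subjects}
    timings["cohort"] = time.perf_counter() - t0

    t0 = _stage("features")
    if config.feature_source == "true":
        feats = {sid: truth.subjects[sid].features for sid in by_id}
    else:
        fmaps, _comp = extract_cohort_features(
            subjects,
            space,
            target_dim=config.target_dim,
            k_ica=config.k_ica,
            symmetry_threshold=config.symmetry_threshold,
            seed=derive_seed(config.master_seed, "ica"),
        )
        feats = {sid: fm.values for sid, fm in fmaps.items()}
    timings["features"] = time.perf_counter() - t0

    split = make_split(
        sorted(by_id),
        config.split_counts,
        seed=derive_seed(config.master_seed, "split"),
    )
    if out_dir:
        split.save(out_dir / "split.yaml")

    tasks = sorted(subjects[0].task_maps)
    hyper = {k: dict(config.hyperparams.get(k, {})) for k in config.model_kinds}

    if config.tune:
        t0 = _stage("tuning")
        hx = np.vstack([feats[sid] for sid in split.hyperopt_ids])
        for task in tasks[:1]:
            hy = np.concatenate([by_id[sid].task_maps[task] for sid in split.hyperopt_ids])
            if "nn" in config.model_kinds:
                tuned = tune_nn(
                    hx, hy, config.tuning_grids.get("nn"), seed=derive_seed(config.master_seed, "tune_nn")
                )
                hyper["nn"].update(tuned.values)
            if "rfbag" in config.model_kinds:
                tuned = tune_rfbag(
                    hx, hy, config.tuning_grids.get("rfbag"), seed=derive_seed(config.master_seed, "tune_rf")
                )
                hyper["rfbag"].update(tuned.values)
        timings["tuning"] = time.perf_counter() - t0

    report: dict = {
        "config_hash": chash,
        "tasks": {},
        "hyperparams": hyper,
        "split": asdict(split),
    }
    rows = []
    for task in tasks:
        train_x = [feats[sid] for sid in split.train_ids]
        train_y = [by_id[sid].task_maps[task] for sid in split.train_ids]
        test_x = [feats[sid] for sid in split.test_ids]
        actual = np.vstack([by_id[sid].task_maps[task] for sid in split.test_ids])
        task_rep: dict = {"models": {}}
        scores: dict[str, np.ndarray] = {}
        for kind in config.model_kinds:
            t0 = _stage(f"train {kind} {task}")
            ens = train_ensemble(
                kind,
                train_x,
                train_y,
                parc,
                hyper.get(kind),
                m=config.m_averages if kind != "glm" else 1,
                seed=derive_seed(config.master_seed, f"train:{kind}:{task}"),
            )
            predicted = np.vstack([predict_ensemble(ens, x, parc) for x in test_x])
            matrix = ev.prediction_matrix(
                predicted, actual, subject_ids=split.test_ids, task=task, model_kind=kind
            )
            dices = []
            for i, sid in enumerate(split.test_ids):
                fit_a = ev.fit_mixture(actual[i])
                fit_p = ev.fit_mixture(predicted[i])
                dices.append(
                    ev.dice(ev.threshold_map(actual[i], fit_a), ev.threshold_map(predicted[i], fit_p))
                )
            task_rep["models"][kind] = {
                "matrix": matrix,
                "normalized_matrix": ev.normalize_matrix(matrix.values),
                "accuracy": ev.prediction_accuracy(matrix),
                "dice": float(np.mean(dices)),
                "per_subject_cc": np.diag(matrix.values),
            }
            scores[kind] = np.diag(matrix.values)
            timings[f"train:{kind}:{task}"] = time.perf_counter() - t0
            rows.append(
                {
                    "task": task,
                    "model": kind,
                    "accuracy": task_rep["models"][kind]["accuracy"],
                    "dice": task_rep["models"][kind]["dice"],
                }
            )
        if len(scores) >= 2 and len(split.test_ids) >= 3:
            task_rep["anova"] = ev.compare_models(scores)
        if config.n_train_grid or config.m_grid:
            t0 = _stage(f"curves {task}")
            task_rep["curves"] = {}
            for kind in config.model_kinds:
                task_rep["curves"][kind] = ev.learning_curve(
                    train_x,
                    train_y,
                    test_x,
                    [by_id[sid].task_maps[task] for sid in split.test_ids],
                    parc,
                    kind,
                    hyper.get(kind),
                    n_train_grid=config.n_train_grid or (len(train_x),),
                    m_grid=config.m_grid or (1,),
                    seed=derive_seed(config.master_seed, f"curve:{kind}:{task}"),
                )
            timings[f"curves:{task}"] = time.perf_counter() - t0
        report["tasks"][task] = task_rep
    report["timings"] = timings
    table = pd.DataFrame(rows)
    report["table"] = table
    if out_dir:
        table.to_csv(out_dir / "report.csv", index=False)
    return report
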