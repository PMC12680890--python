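"""End-to-end orchestration of the five modeling approaches.

One run simulates the full factorial design, extracts the nine echo
features, builds a shared 80:20 split with fivefold CV on the training
side, and trains/evaluates:

* approach 1 — three strain-specific cell-count regressions (9 inputs each),
* approach 2 — one combined regression on echo features alone (9 inputs),
* approach 3 — combined regression + one-hot strain identity (12 inputs),
* approach 4 — approach 3 + ordinal wort concentration (13 inputs),
* approach 5 — softmax strain classifier on echo features (9 inputs),

seven trained models in total.  All randomness flows from a single root
seed split into named substreams (simulate, labels, split, train), so a run
is reproducible end to end from its config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from . import __version__
from .datasets import FEATURE_COLUMNS, SplitPlan, UltrasoundScaler, assemble, make_split
from .io import features_to_frame
from .metrics import crossval_report
from .mlp import CompactMLPClassifier, CompactMLPRegressor
from .processing import PipelineConfig, feature_vector
from .simulate import (
    AcousticParams,
    SampleRecord,
    SimConfig,
    Strain,
    VesselGeometry,
    iter_design_measurements,
    make_gradient_design,
)

__all__ = [
    "ApproachSpec",
    "APPROACHES",
    "RunConfig",
    "build_feature_table",
    "run_approach",
    "run_all",
]

_SUBSTREAMS = ("simulate", "labels", "split", "train")


@dataclass(frozen=True)
class ApproachSpec:
    """Static description of one modeling approach."""

    id: int
    task: str  # "regression" | "classification"
    scope: str  # "per_strain" | "combined"
    input_width: int
    target: str
    description: str


APPROACHES: dict[int, ApproachSpec] = {
    1: ApproachSpec(1, "regression", "per_strain", 9, "measured_cell_count",
                    "strain-specific cell-count models, one per strain"),
    2: ApproachSpec(2, "regression", "combined", 9, "measured_cell_count",
                    "combined cell-count model on echo features only"),
    3: ApproachSpec(3, "regression", "combined", 12, "measured_cell_count",
                    "combined model with one-hot strain identity"),
    4: ApproachSpec(4, "regression", "combined", 13, "measured_cell_count",
                    "combined model with strain identity and ordinal wort level"),
    5: ApproachSpec(5, "classification", "combined", 9, "strain_class",
                    "softmax strain classifier on echo features"),
}


@dataclass
class RunConfig:
    """One config object governs simulation, processing, split and training.

    The default sampling rate of 100 MHz (windows are specified in time
    units, so features are rate-independent up to discretization) keeps a
    full-design run cheap; pass 1e9 for acquisition-rate waveforms.
    """

    replicates: int = 3
    sim: SimConfig = field(default_factory=lambda: SimConfig(sampling_rate=1e8))
    params: AcousticParams = field(default_factory=AcousticParams)
    geometry: VesselGeometry = field(default_factory=VesselGeometry)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    collapse_per_measurement: bool = False
    split_policy: str = "group"  # "group" | "row"
    test_fraction: float = 0.2
    n_folds: int = 5
    target_scale: float = 1e6  # optimize counts in units of 10^6 cells/mL

    @classmethod
    def from_mapping(cls, payload: dict) -> "RunConfig":
        cfg = cls()
        for key in ("replicates", "collapse_per_measurement", "split_policy",
                    "test_fraction", "n_folds", "target_scale"):
            if key in payload:
                setattr(cfg, key, payload[key])
        if "sim" in payload:
            cfg.sim = SimConfig(**payload["sim"])
        if "params" in payload:
            base = dataclasses.asdict(cfg.params)
            base.update(payload["params"])
            cfg.params = AcousticParams(**base)
        if "geometry" in payload:
            cfg.geometry = VesselGeometry(**payload["geometry"])
        if "pipeline" in payload:
            cfg.pipeline = PipelineConfig(**payload["pipeline"])
        return cfg


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS.index(name),))
    )


def _split_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS.index("split"),)).generate_state(1)[0] % (2**31))


def build_feature_table(config: RunConfig, seed: int) -> pd.DataFrame:
    """Simulate the design and extract features, one measurement at a time."""
    label_rng = _substream(seed, "labels")
    design = make_gradient_design(config.replicates, config.params, label_rng)
    sim_rng = _substream(seed, "simulate")

    def extracted():
        for record, scans in iter_design_measurements(
            design, config.params, config.geometry, config.sim, sim_rng
        ):
            yield record, feature_vector(scans, config.pipeline)

    return features_to_frame(extracted(), collapse=config.collapse_per_measurement)


def _model_factory(spec: ApproachSpec, config: RunConfig, seed: int):
    train_seed = _split_seed(seed) ^ 0x5EED ^ spec.id

    def factory():
        if spec.task == "classification":
            net = CompactMLPClassifier(random_state=train_seed)
        else:
            net = CompactMLPRegressor(random_state=train_seed, target_scale=config.target_scale)
        return Pipeline([
            ("scale", UltrasoundScaler(n_scaled=len(FEATURE_COLUMNS))),
            ("net", net),
        ])

    return factory


def _subset_plan(plan: SplitPlan, keep: np.ndarray, reindex: dict[int, int]) -> SplitPlan:
    """Restrict a plan to a row subset and renumber ids to 0..n-1."""
    keep_set = set(int(i) for i in keep)
    train = [reindex[int(i)] for i in plan.train_ids if int(i) in keep_set]
    test = [reindex[int(i)] for i in plan.test_ids if int(i) in keep_set]
    fold_of = {reindex[int(i)]: plan.fold_of[int(i)] for i in plan.train_ids if int(i) in keep_set}
    return SplitPlan(
        train_ids=np.asarray(sorted(train), dtype=int),
        test_ids=np.asarray(sorted(test), dtype=int),
        fold_of=fold_of,
        seed=plan.seed,
        policy=plan.policy,
        n_folds=plan.n_folds,
    )


def run_approach(
    approach_id: int,
    rows: pd.DataFrame,
    plan: SplitPlan,
    config: RunConfig,
    seed: int,
) -> tuple[dict, dict]:
    """Train and evaluate one approach; returns (report block, models).

    Approach 1 expands into three per-strain jobs sharing the run's split
    restricted to each strain's rows.
    """
    if approach_id not in APPROACHES:
        raise ValueError(f"unknown approach {approach_id}; expected 1..5")
    spec = APPROACHES[approach_id]
    rows = rows.reset_index(drop=True)

    def run_one(sub_rows: pd.DataFrame, sub_plan: SplitPlan) -> tuple[dict, object]:
        X, y, schema = assemble(spec.id, sub_rows)
        assert X.shape[1] == spec.input_width
        labels = sorted(np.unique(y).tolist()) if spec.task == "classification" else None
        report, model = crossval_report(
            _model_factory(spec, config, seed), X, y, sub_plan,
            task=spec.task, labels=labels,
        )
        report["schema"] = schema
        return report, model

    block = {"approach": spec.id, "task": spec.task, "description": spec.description,
             "input_width": spec.input_width}
    models: dict[str, object] = {}
    if spec.scope == "per_strain":
        per_strain = {}
        for strain in Strain:
            mask = rows["strain"] == strain.value
            sub = rows[mask].reset_index(drop=True)
            reindex = {int(old): new for new, old in enumerate(rows.index[mask])}
            sub_plan = _subset_plan(plan, rows.index[mask].to_numpy(), reindex)
            report, model = run_one(sub, sub_plan)
            per_strain[strain.value] = report
            models[f"approach1_{strain.value}"] = model
        block["per_strain"] = per_strain
    else:
        report, model = run_one(rows, plan)
        block.update(report)
        models[f"approach{spec.id}"] = model
    return block, models


def run_all(
    config: RunConfig | None = None,
    seed: int = 0,
    approaches: Sequence[int] = (1, 2, 3, 4, 5),
    rows: pd.DataFrame | None = None,
) -> tuple[dict, dict]:
    """Full pipeline on one shared dataset and split; deterministic per seed.

    Returns the run report (JSON-ready) and the trained models keyed by
    approach.  ``rows`` may be supplied to reuse an existing feature table.
    """
    config = config or RunConfig()
    if rows is None:
        rows = build_feature_table(config, seed)
    rows = rows.reset_index(drop=True)
    plan = make_split(
        rows,
        _split_seed(seed),
        group_aware=(config.split_policy == "group"),
        test_fraction=config.test_fraction,
        n_folds=config.n_folds,
    )
    report = {
        "seed": seed,
        "split_policy": plan.policy,
        "n_rows": int(len(rows)),
        "n_measurements": int(rows["measurement_id"].nunique()),
        "environment": {
            "sonoyeast": __version__,
            "python": platform.python_version(),
        },
        "approaches": {},
    }
    all_models: dict[str, object] = {}
    for aid in approaches:
        block, models = run_approach(aid, rows, plan, config, seed)
        report["approaches"][str(aid)] = block
        all_models.update(models)
    return report, all_models


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=float))
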