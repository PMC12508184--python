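"""End-to-end orchestration: clean -> select -> ensemble -> cross-validate.

:func:`run_pipeline` wires the stages together from a single
:class:`RunConfig` (loadable from YAML), propagates one global seed into
every stochastic component, and emits a JSON-serializable run report with
the selected features, convergence history, and per-fold metrics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecqba import ECQBASelector
from .evaluation import ten_fold_cv
from .preprocess import Preprocessor
from .schema import TableSchema, obesity_schema
from .synthdata import SynthSpec, generate_dataset

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_SCHEMA_MISMATCH = 2
EXIT_EMPTY_TABLE = 3
EXIT_BACKEND_MISSING = 4


@dataclass
class RunConfig:
    """Flat nested config for one pipeline run.

    ``input_csv=None`` runs on a freshly generated synthetic table.  Every
    sub-config dict is passed through to the corresponding stage; the global
    ``seed`` feeds each stochastic component.
    """

    input_csv: str | None = None
    output_dir: str | None = None
    seed: int = 0
    n_splits: int = 10
    synth: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    swarm: dict = field(default_factory=dict)
    fitness: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def selector_params(self) -> dict:
        return {**self.fitness, **self.swarm}


def load_table(cfg: RunConfig) -> tuple[pd.DataFrame, TableSchema]:
    if cfg.input_csv is None:
        df, schema, _ = generate_dataset(SynthSpec(seed=cfg.seed, **cfg.synth))
        return df, schema
    df = pd.read_csv(cfg.input_csv)
    schema = obesity_schema()
    missing = [c.name for c in schema.columns if c.name not in df.columns]
    if missing:
        raise KeyError(f"input CSV is missing schema columns: {missing}")
    return df, schema


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute preprocessing, EC-QBA selection, ensemble CV; return the report."""
    t0 = time.time()
    df, schema = load_table(cfg)
    feature_names = schema.feature_names

    # full-data selection pass for the headline feature subset + history
    prep = Preprocessor(schema=schema, **cfg.preprocess)
    clean = prep.fit_transform(df)
    X = clean[feature_names].to_numpy(dtype=float)
    y = clean[schema.label_column].to_numpy(dtype=int)
    selector = ECQBASelector(random_state=cfg.seed, **cfg.selector_params())
    selector.fit(X, y)
    selected = [feature_names[j] for j in selector.get_support(indices=True)]

    cv = ten_fold_cv(
        df,
        schema,
        seed=cfg.seed,
        n_splits=cfg.n_splits,
        preprocessor_params=cfg.preprocess,
        selector_params=cfg.selector_params(),
        ensemble_params=cfg.ensemble,
        **cfg.evaluation,
    )

    report = {
        "seed": cfg.seed,
        "n_rows": int(len(df)),
        "preprocess": prep.report_,
        "selected_features": selected,
        "selected_mask": [int(b) for b in selector.support_],
        "best_fitness": selector.best_fitness_,
        "convergence": [h["best_fitness"] for h in selector.history_],
        "cv": cv.as_dict(),
        "fold_assignment": cv.fold_assignment.tolist(),
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("report written to %s", out / "report.json")
    return report


def save_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
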