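"""Seeded synthetic tabular fixtures with a planted relevant feature subset.

The generator emulates the structure of multi-class obesity-risk tables: a
small set of truly informative continuous features (think weight, height,
age, activity) drives a BMI-like continuous risk score, which is banded at
score quantiles into ordinal classes.  Around that core it plants

* **redundant** features — noisy affine copies (correlation ~0.9) of
  relevant ones, which a size-penalized wrapper should learn to drop,
* **noise** features — independent draws carrying no label signal,
* optional missing cells and optional outliers at a stated magnitude,
  with an exact-count contract and an alteration log for test assertions.

Labels are a pure, deterministic function of the relevant columns; the
ground-truth relevance mask is returned for recovery experiments.  A
separate fixture, :func:`kaggle_schema_fixture`, produces a table with the
exact 16-column obesity schema (string categorical levels, 7-class label)
for preprocessing round-trip tests; its values are drawn from plausible
ranges, not fitted to any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import OBESITY_LEVELS, TableSchema, generic_schema, obesity_schema

#: fixed score coefficients, cycled over the relevant features
_SCORE_COEFS = (1.0, -0.8, 0.6, -0.5, 0.4, -0.3)
_REDUNDANT_RHO = 0.9


@dataclass
class SynthSpec:
    """Generator parameters; defaults are the package's standard test bed.

    16 features total: 4 relevant, 4 redundant copies, 8 pure noise; 600
    rows; 7 balanced classes; clean (no missingness or outliers) unless
    rates are set.
    """

    n_rows: int = 600
    relevant_features: list[str] = field(
        default_factory=lambda: ["rel_weight", "rel_height", "rel_age", "rel_activity"]
    )
    n_redundant: int = 4
    n_noise: int = 8
    n_classes: int = 7
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0
    class_balance: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for r in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if self.class_balance is not None:
            if len(self.class_balance) != self.n_classes:
                raise ValueError("class_balance length must equal n_classes")
            if abs(sum(self.class_balance) - 1.0) > 1e-9:
                raise ValueError("class_balance must sum to 1")

    @property
    def d(self) -> int:
        return len(self.relevant_features) + self.n_redundant + self.n_noise

    @property
    def feature_names(self) -> list[str]:
        return (
            list(self.relevant_features)
            + [f"red_{i}" for i in range(self.n_redundant)]
            + [f"noise_{i}" for i in range(self.n_noise)]
        )


def generate_dataset(
    spec: SynthSpec | None = None,
) -> tuple[pd.DataFrame, TableSchema, np.ndarray]:
    """Generate a table, its schema, and the ground-truth relevance mask.

    Labels are quantile bands of a fixed linear score over the relevant
    columns only, so permuting any redundant or noise column leaves every
    label unchanged.  Contamination (missing cells, outliers) is applied to
    feature columns after label construction.
    """
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    n_rel = len(spec.relevant_features)

    X_rel = rng.standard_normal((spec.n_rows, n_rel))
    coefs = np.array([_SCORE_COEFS[i % len(_SCORE_COEFS)] for i in range(n_rel)])
    score = X_rel @ coefs

    balance = (
        np.array(spec.class_balance)
        if spec.class_balance is not None
        else np.full(spec.n_classes, 1.0 / spec.n_classes)
    )
    cuts = np.quantile(score, np.cumsum(balance)[:-1])
    labels = np.digitize(score, cuts)

    cols = {name: X_rel[:, i] for i, name in enumerate(spec.relevant_features)}
    for i in range(spec.n_redundant):
        parent = X_rel[:, i % n_rel]
        noise = rng.standard_normal(spec.n_rows)
        cols[f"red_{i}"] = _REDUNDANT_RHO * parent + np.sqrt(1 - _REDUNDANT_RHO**2) * noise
    for i in range(spec.n_noise):
        cols[f"noise_{i}"] = rng.standard_normal(spec.n_rows)
    df = pd.DataFrame(cols, columns=spec.feature_names)
    df["label"] = labels

    schema = generic_schema(
        continuous=spec.feature_names, label_column="label", n_classes=spec.n_classes
    )
    if spec.missing_rate > 0:
        df, _ = inject_missing(df, spec.missing_rate, seed=spec.seed + 1,
                               columns=spec.feature_names)
    if spec.outlier_rate > 0:
        df, _ = inject_outliers(df, spec.outlier_rate, spec.outlier_magnitude,
                                seed=spec.seed + 2, columns=spec.feature_names)

    truth = np.array(
        [name in spec.relevant_features for name in spec.feature_names], dtype=bool
    )
    return df, schema, truth


def inject_missing(
    df: pd.DataFrame, rate: float, seed: int = 0, columns: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Blank exactly round(rate x eligible cells) cells; returns the alteration log."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = df.copy()
    columns = columns if columns is not None else list(df.columns)
    n_cells = len(out) * len(columns)
    n_hit = round(rate * n_cells)
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_hit, replace=False)
    log = []
    for idx in flat:
        r, c = divmod(int(idx), len(columns))
        col = columns[c]
        out.loc[out.index[r], col] = np.nan
        log.append((int(out.index[r]), col))
    return out, log


def inject_outliers(
    df: pd.DataFrame,
    rate: float,
    magnitude: float,
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[int, str, float]]]:
    """Displace exactly round(rate x eligible cells) cells beyond the column extremes.

    Each hit cell is moved to (max + magnitude x SD) or (min − magnitude x SD)
    of its column's clean values, sign chosen at random.  Returns the log of
    (row, column, new value).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = df.copy()
    columns = columns if columns is not None else list(df.columns)
    stats = {
        c: (float(out[c].min()), float(out[c].max()), float(out[c].std()))
        for c in columns
    }
    n_cells = len(out) * len(columns)
    n_hit = round(rate * n_cells)
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_hit, replace=False)
    log = []
    for idx in flat:
        r, c = divmod(int(idx), len(columns))
        col = columns[c]
        lo, hi, sd = stats[col]
        val = hi + magnitude * sd if rng.random() < 0.5 else lo - magnitude * sd
        out.loc[out.index[r], col] = val
        log.append((int(out.index[r]), col, float(val)))
    return out, log


def kaggle_schema_fixture(n_rows: int = 200, seed: int = 0) -> pd.DataFrame:
    """A table with the 16-feature obesity schema and string categorical levels.

    Synthetic stand-in for the public obesity-risk layout: values are drawn
    from plausible adult ranges and the 7-class label follows BMI bands of
    the generated height/weight, so preprocessing round-trips (encoding,
    fences, normalization) exercise realistic shapes.  Not fitted to any
    real dataset's marginals.
    """
    rng = np.random.default_rng(seed)
    schema = obesity_schema()
    n = n_rows
    height = rng.uniform(1.45, 1.98, n)
    weight = rng.uniform(39.0, 165.0, n)
    bmi = weight / height**2

    level_names = {v: k for k, v in OBESITY_LEVELS.items()}
    # BMI bands: <18.5 insufficient, <25 normal, <27.5 overweight I,
    # <30 overweight II, <35 obesity I, <40 obesity II, else obesity III
    codes = np.select(
        [bmi < 18.5, bmi < 25, bmi < 27.5, bmi < 30, bmi < 35, bmi < 40],
        [0, 1, 5, 6, 2, 3],
        default=4,
    )

    def pick(levels):
        return rng.choice(levels, size=n)

    df = pd.DataFrame(
        {
            "Gender": pick(["female", "male"]),
            "Age": rng.uniform(16, 61, n).round(1),
            "Height": height.round(3),
            "Weight": weight.round(1),
            "family_history_with_overweight": pick(["no", "yes"]),
            "FAVC": rng.integers(0, 2, n).astype(float),
            "FCVC": pick(["no", "yes"]),
            "NCP": rng.uniform(1, 4, n).round(1),
            "CAEC": pick(["no", "sometimes", "frequently", "always"]),
            "SMOKE": pick(["no", "yes"]),
            "CH2O": rng.uniform(1, 3, n).round(2),
            "SCC": pick(["no", "yes"]),
            "FAF": rng.uniform(0, 3, n).round(2),
            "TUE": rng.uniform(0, 2, n).round(2),
            "CALC": pick(["no", "sometimes", "frequently", "always"]),
            "MTRANS": pick(
                ["walking", "public transport", "bike", "motorbike", "automobile"]
            ),
            "Obesity": [level_names[int(c)] for c in codes],
        },
        columns=[c.name for c in schema.columns],
    )
    return df
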