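"""Preprocessing stage: missing-data handling, encoding, outliers, scaling.

The cleaning pipeline applied before feature selection:

1. drop records whose missing fraction exceeds a threshold (default: strictly
   more than 25% of cells missing),
2. impute remaining gaps — continuous gaps with the mean of the same label
   class, categorical gaps with the column mode,
3. integer-encode categorical string levels via the schema's encoding maps,
4. flag outliers in continuous columns by the Tukey IQR fence
   [Q1 − k·IQR, Q3 + k·IQR] (default k = 1.5) and either remove the offending
   rows or clip the values to the fence,
5. min-max normalize continuous columns to [0, 1].

All statistics (class means, modes, fences, min/max) are learned on the
training table only; :class:`Preprocessor` exposes the usual fit/transform
split so held-out folds never leak into them.  Transforming held-out rows may
drop nothing and may produce values outside [0, 1]; those are counted in the
report rather than clipped (configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import CATEGORICAL, CONTINUOUS, TableSchema

logger = logging.getLogger(__name__)


class EmptyTableError(ValueError):
    """Raised when a filtering step leaves no rows."""


class EncodingError(ValueError):
    """Raised for a categorical level with no code in the encoding map."""


@dataclass
class PreprocessConfig:
    """Knobs for the cleaning pipeline.

    missing_row_threshold: a row is dropped iff its missing fraction is
        STRICTLY greater than this.
    outlier_policy: "remove" deletes offending rows, "clip" winsorizes the
        cell to the violated fence.
    clip_transform: clip continuous cells to [0, 1] when transforming
        held-out rows (default False: out-of-range values are only counted).
    """

    missing_row_threshold: float = 0.25
    iqr_multiplier: float = 1.5
    outlier_policy: str = "remove"
    quantile_method: str = "linear"  # linear interpolation between order stats
    clip_transform: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.missing_row_threshold < 1.0:
            raise ValueError("missing_row_threshold must be in (0, 1)")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")
        if self.outlier_policy not in ("remove", "clip"):
            raise ValueError("outlier_policy must be 'remove' or 'clip'")


@dataclass(frozen=True)
class OutlierBounds:
    """Tukey fence for one continuous column."""

    q1: float
    q3: float
    iqr: float
    lb: float
    ub: float


@dataclass
class NormalizationParams:
    """Per-column min/max learned on the training table."""

    a_min: dict[str, float] = field(default_factory=dict)
    a_max: dict[str, float] = field(default_factory=dict)


def drop_sparse_records(
    df: pd.DataFrame, schema: TableSchema, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Drop rows whose fraction of missing feature cells strictly exceeds the threshold."""
    cfg = cfg or PreprocessConfig()
    if len(df) == 0:
        raise EmptyTableError("input table has no rows")
    feats = [c for c in schema.feature_names if c in df.columns]
    frac = df[feats].isna().mean(axis=1)
    kept = df.loc[frac <= cfg.missing_row_threshold]
    if len(kept) == 0:
        raise EmptyTableError("all rows exceeded the missing-value threshold")
    return kept.copy()


def _column_mode(s: pd.Series):
    m = s.mode(dropna=True)
    return m.iloc[0] if len(m) else np.nan


class _ImputeStats:
    """Class-conditional means for continuous columns, modes for categoricals."""

    def __init__(self) -> None:
        self.class_means: dict[str, dict[Any, float]] = {}
        self.global_mean: dict[str, float] = {}
        self.mode: dict[str, Any] = {}

    @classmethod
    def fit(cls, df: pd.DataFrame, schema: TableSchema) -> "_ImputeStats":
        st = cls()
        y = df[schema.label_column]
        for name in schema.continuous_features():
            if name not in df.columns:
                continue
            st.global_mean[name] = float(df[name].mean())
            st.class_means[name] = {
                k: float(v) for k, v in df.groupby(y, observed=True)[name].mean().items()
            }
        for name in schema.categorical_features():
            if name in df.columns:
                st.mode[name] = _column_mode(df[name])
        return st


def impute_missing(
    df: pd.DataFrame,
    schema: TableSchema,
    stats: _ImputeStats | None = None,
    counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fill every missing cell.

    Continuous gaps take the mean of observed values with the same class label
    (falling back to the global column mean when a class has none, or when no
    labels are available at inference time); categorical gaps take the column
    mode.  Pass ``stats`` fitted on training data to impute held-out rows.
    """
    out = df.copy()
    use_labels = schema.label_column in out.columns and stats is None
    if stats is None:
        if not use_labels:
            raise ValueError("training-mode imputation needs the label column")
        stats = _ImputeStats.fit(out, schema)
    y = out[schema.label_column] if schema.label_column in out.columns else None

    for name in schema.continuous_features():
        if name not in out.columns:
            continue
        miss = out[name].isna()
        if not miss.any():
            continue
        if counts is not None:
            counts[name] = counts.get(name, 0) + int(miss.sum())
        fallback = stats.global_mean.get(name, np.nan)
        if y is not None and name in stats.class_means:
            fill = y.map(stats.class_means[name])
            missing_class = miss & fill.isna()
            if missing_class.any():
                logger.warning(
                    "no class mean for %d cells in %r; using global mean",
                    int(missing_class.sum()), name,
                )
            fill = fill.fillna(fallback)
            out.loc[miss, name] = fill[miss]
        else:
            out.loc[miss, name] = fallback
    for name in schema.categorical_features():
        if name not in out.columns:
            continue
        miss = out[name].isna()
        if miss.any():
            if counts is not None:
                counts[name] = counts.get(name, 0) + int(miss.sum())
            out.loc[miss, name] = stats.mode.get(name)
    return out


def encode_table(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Replace categorical string levels by their integer codes (idempotent).

    Cells already holding a code inside the map's range pass through, so
    encoding an encoded table is a no-op.  Unknown levels raise
    :class:`EncodingError` naming the column and level.
    """
    out = df.copy()
    for col in schema.columns:
        if col.kind != CATEGORICAL or col.name not in out.columns:
            continue
        if col.encoding is None:
            raise EncodingError(f"categorical column {col.name!r} has no encoding map")
        codes = set(col.encoding.values())

        def _map(v, col=col, codes=codes):
            if pd.isna(v):
                return v
            if isinstance(v, str):
                key = v.strip().lower()
                if key in col.encoding:
                    return col.encoding[key]
                raise EncodingError(f"unmapped level {v!r} in column {col.name!r}")
            iv = int(v)
            if iv in codes and iv == v:
                return iv
            raise EncodingError(f"unmapped level {v!r} in column {col.name!r}")

        out[col.name] = out[col.name].map(_map)
    return out


def compute_iqr_bounds(
    values, cfg: PreprocessConfig | None = None
) -> OutlierBounds:
    """Tukey fence of one column under linear-interpolation quantiles."""
    cfg = cfg or PreprocessConfig()
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 4:
        raise ValueError(f"need >= 4 values to estimate quartiles, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=cfg.quantile_method)
    iqr = q3 - q1
    return OutlierBounds(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lb=float(q1 - cfg.iqr_multiplier * iqr),
        ub=float(q3 + cfg.iqr_multiplier * iqr),
    )


def apply_outlier_policy(
    df: pd.DataFrame,
    bounds: dict[str, OutlierBounds],
    cfg: PreprocessConfig | None = None,
    counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Remove rows (or clip cells) with continuous values outside the fences."""
    cfg = cfg or PreprocessConfig()
    out = df.copy()
    if cfg.outlier_policy == "remove":
        keep = pd.Series(True, index=out.index)
        for name, b in bounds.items():
            if name not in out.columns:
                continue
            bad = (out[name] < b.lb) | (out[name] > b.ub)
            if counts is not None:
                counts[name] = counts.get(name, 0) + int(bad.sum())
            keep &= ~bad.fillna(False)
        out = out.loc[keep]
        if len(out) == 0:
            raise EmptyTableError("outlier removal left no rows")
        return out.copy()
    for name, b in bounds.items():
        if name not in out.columns:
            continue
        low = out[name] < b.lb
        high = out[name] > b.ub
        if counts is not None:
            counts[name] = counts.get(name, 0) + int(low.sum() + high.sum())
        out.loc[low, name] = b.lb
        out.loc[high, name] = b.ub
    return out


def fit_minmax(df: pd.DataFrame, schema: TableSchema) -> NormalizationParams:
    params = NormalizationParams()
    for name in schema.continuous_features():
        if name not in df.columns:
            continue
        params.a_min[name] = float(df[name].min())
        params.a_max[name] = float(df[name].max())
    return params


def apply_minmax(
    df: pd.DataFrame,
    params: NormalizationParams,
    clip: bool = False,
    out_of_range: dict[str, int] | None = None,
) -> pd.DataFrame:
    """A_norm = (a − a_min)/(a_max − a_min); constant columns map to 0."""
    out = df.copy()
    for name, lo in params.a_min.items():
        if name not in out.columns:
            continue
        hi = params.a_max[name]
        if hi == lo:
            warnings.warn(f"constant column {name!r}: normalized to 0", stacklevel=2)
            out[name] = 0.0
            continue
        scaled = (out[name].astype(float) - lo) / (hi - lo)
        if out_of_range is not None:
            n_out = int(((scaled < 0) | (scaled > 1)).sum())
            if n_out:
                out_of_range[name] = out_of_range.get(name, 0) + n_out
        out[name] = scaled.clip(0.0, 1.0) if clip else scaled
    return out


class Preprocessor(BaseEstimator, TransformerMixin):
    """Fit/transform wrapper over the full cleaning chain.

    ``fit_transform`` on a training table runs the whole chain (which may drop
    rows); ``transform`` on held-out rows reuses the fitted statistics, never
    drops rows, and imputes with the global statistics learned at fit time.

    Parameters mirror :class:`PreprocessConfig`.  Fitted state:

    - ``impute_stats_`` : class means / global means / modes
    - ``bounds_`` : per-column :class:`OutlierBounds`
    - ``norm_params_`` : per-column min/max
    - ``report_`` : counts of rows dropped, cells imputed, outliers handled
    """

    def __init__(
        self,
        schema: TableSchema | None = None,
        missing_row_threshold: float = 0.25,
        iqr_multiplier: float = 1.5,
        outlier_policy: str = "remove",
        clip_transform: bool = False,
    ) -> None:
        self.schema = schema
        self.missing_row_threshold = missing_row_threshold
        self.iqr_multiplier = iqr_multiplier
        self.outlier_policy = outlier_policy
        self.clip_transform = clip_transform

    def _cfg(self) -> PreprocessConfig:
        return PreprocessConfig(
            missing_row_threshold=self.missing_row_threshold,
            iqr_multiplier=self.iqr_multiplier,
            outlier_policy=self.outlier_policy,
            clip_transform=self.clip_transform,
        )

    def _schema(self) -> TableSchema:
        if self.schema is None:
            raise ValueError("Preprocessor needs a schema")
        return self.schema

    def fit(self, X: pd.DataFrame, y=None) -> "Preprocessor":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        schema, cfg = self._schema(), self._cfg()
        report: dict[str, Any] = {"n_input_rows": int(len(X))}
        df = drop_sparse_records(X, schema, cfg)
        report["rows_dropped_sparse"] = int(len(X) - len(df))
        df = encode_table(df, schema)
        imputed: dict[str, int] = {}
        df = impute_missing(df, schema, counts=imputed)
        # store inference-time statistics from the cleaned training table
        self.impute_stats_ = _ImputeStats.fit(df, schema)
        report["cells_imputed"] = imputed
        outliers: dict[str, int] = {}
        self.bounds_ = {
            name: compute_iqr_bounds(df[name], cfg)
            for name in schema.continuous_features()
            if name in df.columns and df[name].notna().sum() >= 4
        }
        n_before = len(df)
        df = apply_outlier_policy(df, self.bounds_, cfg, counts=outliers)
        report["rows_dropped_outliers"] = int(n_before - len(df))
        report["outlier_cells"] = outliers
        self.norm_params_ = fit_minmax(df, schema)
        df = apply_minmax(df, self.norm_params_)
        report["n_output_rows"] = int(len(df))
        self.report_ = report
        return df

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "norm_params_"):
            raise ValueError("Preprocessor is not fitted")
        schema = self._schema()
        df = encode_table(X, schema)
        df = impute_missing(df, schema, stats=self.impute_stats_)
        oor: dict[str, int] = {}
        df = apply_minmax(
            df, self.norm_params_, clip=self.clip_transform, out_of_range=oor
        )
        self.transform_out_of_range_ = oor
        return df
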