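"""Column schemas for tabular risk datasets.

A :class:`TableSchema` pairs a pandas DataFrame with the metadata the rest of
the package needs: which columns are continuous, which are categorical (and
how their string levels map to integer codes), and which column carries the
class label.  The default :func:`obesity_schema` reproduces the 16-feature
demographic/behavioral/lifestyle layout of the public obesity-risk datasets
this package targets, with 7 ordinal obesity classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ColumnSpec:
    """One column: its name, kind, and (for categoricals) level -> code map."""

    name: str
    kind: str  # CONTINUOUS or CATEGORICAL
    encoding: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass
class TableSchema:
    """Ordered column specs plus the label column name."""

    columns: list[ColumnSpec]
    label_column: str

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        if self.label_column not in names:
            raise ValueError(f"label column {self.label_column!r} not in schema")

    @property
    def feature_columns(self) -> list[ColumnSpec]:
        return [c for c in self.columns if c.name != self.label_column]

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.feature_columns]

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def continuous_features(self) -> list[str]:
        return [c.name for c in self.feature_columns if c.kind == CONTINUOUS]

    def categorical_features(self) -> list[str]:
        return [c.name for c in self.feature_columns if c.kind == CATEGORICAL]


#: Integer codes for the 7 obesity classes, from insufficient weight upward.
OBESITY_LEVELS: dict[str, int] = {
    "insufficient weight": 0,
    "normal weight": 1,
    "obesity type i": 2,
    "obesity type ii": 3,
    "obesity type iii": 4,
    "overweight level i": 5,
    "overweight level ii": 6,
}

_YES_NO = {"no": 0, "yes": 1}
_FREQ4 = {"no": 0, "sometimes": 1, "frequently": 2, "always": 3}


def obesity_schema() -> TableSchema:
    """Schema of the 16-feature obesity-risk layout with its encoding maps.

    Categorical encodings: Gender 0=female/1=male; yes/no flags 0/1; CAEC and
    CALC on the 4-level no/sometimes/frequently/always scale; MTRANS walking=0
    through automobile=4; the label on the 7-class obesity scale.
    """
    cols = [
        ColumnSpec("Gender", CATEGORICAL, {"female": 0, "male": 1}),
        ColumnSpec("Age", CONTINUOUS),
        ColumnSpec("Height", CONTINUOUS),
        ColumnSpec("Weight", CONTINUOUS),
        ColumnSpec("family_history_with_overweight", CATEGORICAL, dict(_YES_NO)),
        ColumnSpec("FAVC", CONTINUOUS),
        ColumnSpec("FCVC", CATEGORICAL, dict(_YES_NO)),
        ColumnSpec("NCP", CONTINUOUS),
        ColumnSpec("CAEC", CATEGORICAL, dict(_FREQ4)),
        ColumnSpec("SMOKE", CATEGORICAL, dict(_YES_NO)),
        ColumnSpec("CH2O", CONTINUOUS),
        ColumnSpec("SCC", CATEGORICAL, dict(_YES_NO)),
        ColumnSpec("FAF", CONTINUOUS),
        ColumnSpec("TUE", CONTINUOUS),
        ColumnSpec("CALC", CATEGORICAL, dict(_FREQ4)),
        ColumnSpec("MTRANS", CATEGORICAL, {
            "walking": 0,
            "public transport": 1,
            "bike": 2,
            "motorbike": 3,
            "automobile": 4,
        }),
        ColumnSpec("Obesity", CATEGORICAL, dict(OBESITY_LEVELS)),
    ]
    return TableSchema(columns=cols, label_column="Obesity")


def generic_schema(
    continuous: list[str],
    categorical: dict[str, dict[str, int]] | None = None,
    label_column: str = "label",
    n_classes: int = 7,
) -> TableSchema:
    """Build a schema for arbitrary feature names (used by the synthetic generator)."""
    categorical = categorical or {}
    cols = [ColumnSpec(n, CONTINUOUS) for n in continuous]
    cols += [ColumnSpec(n, CATEGORICAL, enc) for n, enc in categorical.items()]
    cols.append(
        ColumnSpec(label_column, CATEGORICAL, {str(i): i for i in range(n_classes)})
    )
    return TableSchema(columns=cols, label_column=label_column)
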