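"""Schema-typed tabular data with a binary class column.

Datasets are CSV tables whose columns are declared by a list of
:class:`FeatureSchema` (categorical with an explicit level set, or
continuous) plus one class column.  Preprocessing follows two fixed
policies: a missing categorical value becomes a dedicated extra level
(``__missing__``), while a row with a missing continuous value is dropped.
Multi-category class variables are made binary by explicit category
merging.  Internally the minority class is "+" and the majority "−".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

MISSING_LEVEL = "__missing__"

#: internal class labels: minority / majority
POS = "+"
NEG = "-"


class PreconditionError(ValueError):
    """An input violates a documented precondition (CLI exit code 2)."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declares one feature: its name, kind and (if categorical) levels."""

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise PreconditionError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise PreconditionError(f"categorical feature {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise PreconditionError(f"duplicate levels for {self.name!r}")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        elif self.levels is not None:
            raise PreconditionError(f"continuous feature {self.name!r} must not declare levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"


@dataclass(frozen=True)
class ClassBalance:
    """Class counts and proportions of a binary dataset; minority is '+'."""

    M: int
    m_plus: int
    m_minus: int

    def __post_init__(self) -> None:
        if self.m_plus + self.m_minus != self.M:
            raise PreconditionError("class counts do not sum to M")
        if not (0 < self.m_plus <= self.m_minus):
            raise PreconditionError(
                "minority count must be positive and no larger than the majority count"
            )
        if self.p_plus >= 0.5:
            raise PreconditionError("minority proportion must be < 0.5")

    @property
    def p_plus(self) -> float:
        return self.m_plus / self.M

    @property
    def p_minus(self) -> float:
        return self.m_minus / self.M


@dataclass
class DatasetTable:
    """A validated table: feature columns per schema plus one class column."""

    features: list[FeatureSchema]
    class_name: str
    df: pd.DataFrame
    provenance: str = "original"  # original | synthetic | enlarged
    label_map: dict[str, str] | None = None  # external label -> internal label

    def __post_init__(self) -> None:
        expected = [f.name for f in self.features] + [self.class_name]
        if list(self.df.columns) != expected:
            self.df = self.df.loc[:, expected]
        self.df = self.df.reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def schema_of(self, name: str) -> FeatureSchema:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def X(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    @property
    def y(self) -> pd.Series:
        return self.df[self.class_name]

    def validate(self, require_binary: bool = True) -> None:
        for f in self.features:
            col = self.df[f.name]
            if f.is_categorical:
                bad = set(col.unique()) - set(f.levels)
                if bad:
                    raise PreconditionError(
                        f"values {sorted(bad)!r} of {f.name!r} outside declared levels"
                    )
            else:
                vals = col.to_numpy(dtype=float)
                if not np.all(np.isfinite(vals)):
                    raise PreconditionError(f"non-finite value in continuous feature {f.name!r}")
        labels = self.df[self.class_name].unique()
        if require_binary and len(labels) != 2:
            raise PreconditionError(
                f"class not binary: {len(labels)} labels {sorted(map(str, labels))!r}"
            )

    def subset(self, mask) -> "DatasetTable":
        return replace(self, df=self.df.loc[mask].reset_index(drop=True))


def load_dataset(
    path,
    schema: list[FeatureSchema],
    class_name: str,
    missing_token: str = "?",
    strict: bool = True,
    require_binary: bool = True,
) -> DatasetTable:
    """Read a CSV into a :class:`DatasetTable`, applying the missing-value policy.

    Categorical cells equal to ``missing_token`` are replaced by the dedicated
    level ``__missing__`` (appended to that feature's level set); rows with a
    missing continuous cell are dropped.  In strict mode (default) a
    categorical value outside the declared levels is an error.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = {f.name for f in schema} | {class_name}
    got = set(raw.columns)
    if got != expected:
        raise PreconditionError(
            f"column mismatch: unexpected {sorted(got - expected)}, missing {sorted(expected - got)}"
        )

    out_schema: list[FeatureSchema] = []
    keep = pd.Series(True, index=raw.index)
    for f in schema:
        if not f.is_categorical and (raw[f.name] == missing_token).any():
            keep &= raw[f.name] != missing_token
    raw = raw.loc[keep]
    if raw.empty:
        raise PreconditionError("empty table after dropping rows with missing continuous values")

    cols = {}
    for f in schema:
        col = raw[f.name]
        if f.is_categorical:
            levels = f.levels
            if (col == missing_token).any():
                if MISSING_LEVEL in levels:
                    raise PreconditionError(
                        f"{f.name!r} already declares the reserved level {MISSING_LEVEL!r}"
                    )
                levels = levels + (MISSING_LEVEL,)
                col = col.replace(missing_token, MISSING_LEVEL)
            if strict:
                bad = set(col.unique()) - set(levels)
                if bad:
                    raise PreconditionError(
                        f"values {sorted(bad)!r} of {f.name!r} outside declared levels"
                    )
            out_schema.append(FeatureSchema(f.name, "categorical", levels))
            cols[f.name] = col.astype(str)
        else:
            out_schema.append(f)
            cols[f.name] = col.astype(float)
    cols[class_name] = raw[class_name].astype(str)

    table = DatasetTable(out_schema, class_name, pd.DataFrame(cols))
    table.validate(require_binary=require_binary)
    return table


def binarize_class(table: DatasetTable, merge_map: dict[str, str]) -> DatasetTable:
    """Merge class categories into exactly two labels; row order preserved."""
    observed = set(table.df[table.class_name].unique())
    unmapped = observed - set(merge_map)
    if unmapped:
        raise PreconditionError(f"merge_map leaves labels unmapped: {sorted(unmapped)}")
    targets = {merge_map[l] for l in observed}
    if len(targets) != 2:
        raise PreconditionError(f"merge_map collapses observed labels to {len(targets)} class(es)")
    df = table.df.copy()
    df[table.class_name] = df[table.class_name].map(merge_map)
    out = replace(table, df=df, label_map=dict(merge_map))
    out.validate()
    return out


def class_balance(table: DatasetTable, minority_label: str) -> ClassBalance:
    """Counts and proportions (M, m+, m−, p+, p−) with '+' the minority."""
    y = table.df[table.class_name]
    m_plus = int((y == minority_label).sum())
    if m_plus == 0:
        raise PreconditionError(f"minority label {minority_label!r} absent from the class column")
    m_minus = len(y) - m_plus
    if m_plus > m_minus:
        raise PreconditionError(f"label {minority_label!r} is the majority, not the minority")
    return ClassBalance(M=len(y), m_plus=m_plus, m_minus=m_minus)


def write_dataset(table: DatasetTable, path) -> None:
    """Write CSV (UTF-8, '.' decimal) plus a ``.meta.json`` sidecar.

    Continuous values are written with ``repr`` round-trip fidelity so that
    ``load_dataset(write_dataset(t))`` is the identity on valid tables.
    """
    table.df.to_csv(path, index=False)
    meta = {
        "class_name": table.class_name,
        "provenance": table.provenance,
        "label_map": table.label_map,
        "features": [
            {"name": f.name, "kind": f.kind, "levels": list(f.levels) if f.levels else None}
            for f in table.features
        ],
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def infer_schema(X: pd.DataFrame) -> list[FeatureSchema]:
    """Infer a schema from dtypes: numeric → continuous, else categorical."""
    out = []
    for name in X.columns:
        if pd.api.types.is_numeric_dtype(X[name]):
            out.append(FeatureSchema(name, "continuous"))
        else:
            levels = tuple(sorted(map(str, pd.unique(X[name].astype(str)))))
            out.append(FeatureSchema(name, "categorical", levels))
    return out


# -- schema sidecar (YAML or JSON) --------------------------------------

def save_schema(path, features: list[FeatureSchema], class_name: str,
                minority_label: str | None = None) -> None:
    doc = {
        "class_name": class_name,
        "minority_label": minority_label,
        "features": [
            {"name": f.name, "kind": f.kind,
             **({"levels": list(f.levels)} if f.levels else {})}
            for f in features
        ],
    }
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_schema(path) -> tuple[list[FeatureSchema], str, str | None]:
    with open(path) as fh:
        doc = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    feats = [
        FeatureSchema(d["name"], d["kind"],
                      tuple(d["levels"]) if d.get("levels") else None)
        for d in doc["features"]
    ]
    return feats, doc["class_name"], doc.get("minority_label")
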