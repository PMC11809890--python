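"""Unit-level analysis table: loading, validation, and design encoding.

The analysis unit is one woman with two binary outcomes — ``y1`` (at least
four antenatal-care contacts) and ``y2`` (delivery at a health facility) —
a zone (cluster) identifier, categorical covariates, and a DHS-style
sampling weight.  All coding conventions live here: outcomes are 1/0 as in
the survey definitions, categoricals are dummy-coded against declared
reference levels, and column order is explicit configuration so fitted
coefficient tables are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "CodingError",
    "CategoricalSpec",
    "ColumnMap",
    "AnalysisTable",
    "DesignMatrices",
    "ValidationReport",
    "load_table",
    "save_table",
    "encode_design",
    "decode_design",
    "validate",
    "schema_from_dict",
    "schema_to_dict",
    "load_schema",
]

#: sentinel level under which missing covariate values are retained for
#: descriptive tables; rows at this level are excluded from model fitting.
MISSING_LEVEL = "missing"


class SchemaError(ValueError):
    """A required column or categorical specification is absent."""


class CodingError(ValueError):
    """A value violates the declared coding (non-binary outcome, unknown level...)."""


@dataclass(frozen=True)
class CategoricalSpec:
    """Declared levels and reference category of one covariate."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: duplicate levels {self.levels}")
        if self.reference not in self.levels:
            raise SchemaError(
                f"{self.name}: reference {self.reference!r} not among levels")

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from external CSV column names to the canonical roles."""

    y1: str = "anc4"
    y2: str = "facility_delivery"
    cluster: str = "zone"
    weight: str = "weight"


@dataclass
class AnalysisTable:
    """Validated unit-level table with canonical columns.

    ``data`` holds columns ``y1``, ``y2`` (int 0/1), ``cluster`` (str),
    ``weight`` (float >= 0) plus one string column per covariate in
    ``schema``.  Covariate values are members of the declared level set or
    the explicit ``"missing"`` level.
    """

    data: pd.DataFrame
    schema: tuple[CategoricalSpec, ...]
    load_report: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        for col in ("y1", "y2", "cluster", "weight"):
            if col not in df.columns:
                raise SchemaError(f"canonical column {col!r} missing")
        for col in ("y1", "y2"):
            vals = df[col].to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                i = int(np.argmax(bad))
                raise CodingError(
                    f"non-binary value {vals[i]!r} in outcome {col!r} at row {i}")
        if (df["weight"].to_numpy(float) < 0).any():
            raise CodingError("negative sampling weight")
        if df["cluster"].isna().any():
            raise CodingError("unit without a cluster id")
        for spec in self.schema:
            if spec.name not in df.columns:
                raise SchemaError(f"covariate column {spec.name!r} missing")
            allowed = set(spec.levels) | {MISSING_LEVEL}
            observed = set(df[spec.name].astype(str).unique())
            extra = observed - allowed
            if extra:
                raise CodingError(
                    f"covariate {spec.name!r} has undeclared level(s) {sorted(extra)}")

    @property
    def n_units(self) -> int:
        return len(self.data)

    @property
    def n_clusters(self) -> int:
        return self.data["cluster"].nunique()

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.schema)

    def spec(self, name: str) -> CategoricalSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise SchemaError(f"no categorical spec for {name!r}")


@dataclass
class DesignMatrices:
    """Dummy-coded design for the two marginal predictors.

    ``X1``/``X2`` each start with an intercept column of ones followed by
    ``k - 1`` indicator columns per categorical (declaration order, then
    declared level order); the reference level maps to all-zero indicators.
    ``cluster_index`` maps each retained row to a cluster ordinal, and
    ``row_index`` gives the positional index of retained rows in the source
    table (rows with a ``"missing"`` covariate value are excluded).
    """

    X1: np.ndarray
    X2: np.ndarray
    names1: tuple[str, ...]
    names2: tuple[str, ...]
    cluster_index: np.ndarray
    cluster_ids: tuple[str, ...]
    row_index: np.ndarray
    n_dropped_missing: int = 0

    @property
    def n_units(self) -> int:
        return self.X1.shape[0]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def _build_matrix(df: pd.DataFrame, covariates, schema_map):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in schema_map:
            raise SchemaError(f"no categorical spec for covariate {cov!r}")
        spec = schema_map[cov]
        values = df[cov].to_numpy()
        for level in spec.non_reference:
            cols.append((values == level).astype(float))
            names.append(f"{cov}[{level}]")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, tuple(names)


def encode_design(table: AnalysisTable, covariates1, covariates2,
                  schema=None) -> DesignMatrices:
    """Dummy-code the table into per-outcome design matrices.

    Rows with a ``"missing"`` value in any covariate used by either
    predictor are dropped (counted in ``n_dropped_missing``); cluster ids
    are ordinalized in sorted order for determinism.
    """
    schema = tuple(schema) if schema is not None else table.schema
    schema_map = {s.name: s for s in schema}
    used = list(dict.fromkeys(list(covariates1) + list(covariates2)))
    for cov in used:
        if cov not in schema_map:
            raise SchemaError(f"no categorical spec for covariate {cov!r}")

    df = table.data
    keep = np.ones(len(df), dtype=bool)
    for cov in used:
        keep &= df[cov].to_numpy() != MISSING_LEVEL
    sub = df.loc[keep]
    X1, names1 = _build_matrix(sub, covariates1, schema_map)
    X2, names2 = _build_matrix(sub, covariates2, schema_map)
    cluster_ids, cluster_index = np.unique(
        sub["cluster"].astype(str).to_numpy(), return_inverse=True)
    return DesignMatrices(
        X1=X1, X2=X2, names1=names1, names2=names2,
        cluster_index=cluster_index.astype(np.int64),
        cluster_ids=tuple(cluster_ids),
        row_index=np.flatnonzero(keep),
        n_dropped_missing=int((~keep).sum()),
    )


def decode_design(X: np.ndarray, names, schema) -> pd.DataFrame:
    """Recover category labels from an encoded matrix (encoding inverse)."""
    schema_map = {s.name: s for s in schema}
    out = {}
    name_to_col = {n: j for j, n in enumerate(names)}
    covs = []
    for n in names:
        if n == "intercept":
            continue
        cov = n.split("[", 1)[0]
        if cov not in covs:
            covs.append(cov)
    for cov in covs:
        spec = schema_map[cov]
        labels = np.full(X.shape[0], spec.reference, dtype=object)
        for level in spec.non_reference:
            j = name_to_col[f"{cov}[{level}]"]
            labels[X[:, j] == 1.0] = level
        out[cov] = labels
    return pd.DataFrame(out)


def load_table(path, schema, columns: ColumnMap | None = None) -> AnalysisTable:
    """Load and validate a delimited unit-level file.

    Rows with a missing outcome or cluster id are dropped and counted in
    ``AnalysisTable.load_report``; missing covariate cells are recoded to
    the explicit ``"missing"`` level (kept for descriptives, excluded from
    design encoding).
    """
    columns = columns or ColumnMap()
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    mandatory = {
        columns.y1: "y1", columns.y2: "y2",
        columns.cluster: "cluster", columns.weight: "weight",
    }
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    for spec in schema:
        if spec.name not in df.columns:
            raise SchemaError(f"covariate column {spec.name!r} missing from {path}")

    n_input = len(df)
    df = df.rename(columns=mandatory)
    complete = df["y1"].notna() & df["y2"].notna() & df["cluster"].notna()
    dropped = int((~complete).sum())
    df = df.loc[complete].reset_index(drop=True)

    for col in ("y1", "y2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin((0, 1))
        if bad.any():
            i = int(bad.idxmax())
            raise CodingError(
                f"non-binary value {df[col].iloc[i]!r} in outcome column "
                f"{col!r} at data row {i}")
        df[col] = vals.astype(int)
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce").fillna(0.0)
    df["cluster"] = df["cluster"].astype(str)
    for spec in schema:
        df[spec.name] = df[spec.name].fillna(MISSING_LEVEL).astype(str)

    keep_cols = ["y1", "y2", "cluster", "weight"] + [s.name for s in schema]
    table = AnalysisTable(df[keep_cols].copy(), tuple(schema))
    table.load_report = {
        "n_input": n_input,
        "drop_count": dropped,
        "n_retained": len(df),
    }
    return table


def save_table(table: AnalysisTable, path, columns: ColumnMap | None = None) -> None:
    """Write the table as CSV using the external column names."""
    columns = columns or ColumnMap()
    df = table.data.rename(columns={
        "y1": columns.y1, "y2": columns.y2,
        "cluster": columns.cluster, "weight": columns.weight,
    })
    df.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Structural summary of an analysis table (reporting only)."""

    n_units: int
    n_clusters: int
    cluster_sizes: dict
    prevalence_y1: float
    prevalence_y2: float
    zero_weight_count: int
    single_level_covariates: list
    warnings: list

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def validate(table: AnalysisTable) -> ValidationReport:
    """Per-cluster sizes, weighted outcome prevalences, and identifiability flags."""
    df = table.data
    w = df["weight"].to_numpy(float)
    wt = w.sum()
    sizes = df.groupby("cluster").size().to_dict()
    warnings = []
    if len(sizes) < 2:
        warnings.append("clusters=1: insufficient for any multilevel fit")
    single = []
    for spec in table.schema:
        observed = df.loc[df[spec.name] != MISSING_LEVEL, spec.name].nunique()
        if observed <= 1:
            single.append(spec.name)
            warnings.append(
                f"covariate {spec.name!r} has a single observed level: "
                "non-identifiable, excluded from fitting")
    prev1 = float((w * df["y1"]).sum() / wt) if wt > 0 else float("nan")
    prev2 = float((w * df["y2"]).sum() / wt) if wt > 0 else float("nan")
    return ValidationReport(
        n_units=len(df),
        n_clusters=len(sizes),
        cluster_sizes={str(k): int(v) for k, v in sizes.items()},
        prevalence_y1=prev1,
        prevalence_y2=prev2,
        zero_weight_count=int((w == 0).sum()),
        single_level_covariates=single,
        warnings=warnings,
    )


def schema_to_dict(schema) -> list:
    return [
        {"name": s.name, "levels": list(s.levels), "reference": s.reference}
        for s in schema
    ]


def schema_from_dict(items) -> tuple[CategoricalSpec, ...]:
    return tuple(
        CategoricalSpec(d["name"], tuple(d["levels"]), d["reference"])
        for d in items
    )


def load_schema(path) -> tuple[CategoricalSpec, ...]:
    """Read covariate specs from a YAML/JSON config file.

    Accepts either a bare list of specs or a mapping with a ``covariates``
    key (the CLI run-config layout).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = data["covariates"]
    return schema_from_dict(data)
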