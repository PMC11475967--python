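"""Reading, cleaning and numeric encoding of protein-peptide descriptor tables.

A feature table is one row per patient sample and ~30 mixed-type descriptor
columns (sizes, interface areas, molecular weights, aromaticity, instability,
isoelectric points, cluster flags, plus identifier/sequence/text columns),
together with one or more numeric severity-score targets (motor / total
UPDRS-style). The model downstream is defined on real-valued vectors, so
text, sequence and identifier columns are dropped, categoricals are
integer-coded, booleans become 0/1, constant columns are removed, and the
surviving columns are z-scored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_KINDS = frozenset({"numeric", "categorical", "text", "identifier"})


@dataclass
class FeatureTable:
    """A parsed descriptor table plus its declared column schema."""

    df: pd.DataFrame
    column_spec: dict[str, str]           # column name -> kind
    target_columns: tuple[str, ...]
    undeclared_columns: tuple[str, ...] = ()
    clean_report: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """Dense real-valued sample x feature matrix, optionally standardized."""

    values: np.ndarray                    # (M, N) float64
    feature_names: list[str]
    sample_ids: list
    standardized: bool = False
    scale_means: np.ndarray | None = None
    scale_sds: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ScoreVector:
    """Target scores with optional z-scaling that can be inverted exactly."""

    values: np.ndarray
    name: str = "target"
    standardized: bool = False
    scale_mean: float = 0.0
    scale_sd: float = 1.0

    def __len__(self) -> int:
        return len(self.values)

    def standardize(self, mean: float | None = None,
                    sd: float | None = None) -> "ScoreVector":
        if self.standardized:
            return self
        mean = float(np.mean(self.values)) if mean is None else float(mean)
        sd = float(np.std(self.values)) if sd is None else float(sd)
        if sd == 0:
            sd = 1.0
        return ScoreVector((self.values - mean) / sd, self.name, True, mean, sd)

    def unstandardize(self) -> "ScoreVector":
        if not self.standardized:
            return self
        return ScoreVector(self.values * self.scale_sd + self.scale_mean,
                           self.name, False, 0.0, 1.0)


def _check_arity(path: Path) -> None:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        width = len(header)
        for i, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != width:
                raise ValueError(
                    f"{path}: row {i} has {len(row)} fields, header has {width}"
                )


def read_feature_table(path,
                       column_spec: Mapping[str, str],
                       target_column: str | Sequence[str]) -> FeatureTable:
    """Read a delimited table and attach the declared schema.

    Columns present in the file but absent from ``column_spec`` are retained
    and flagged as identifiers. A missing target column, or a data row whose
    field count differs from the header, is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    targets = (target_column,) if isinstance(target_column, str) else tuple(target_column)
    for name, kind in column_spec.items():
        if kind not in VALID_KINDS:
            raise ValueError(f"column {name!r}: unknown kind {kind!r}")
    _check_arity(path)
    df = pd.read_csv(path)
    for t in targets:
        if t not in df.columns:
            raise ValueError(f"target column {t!r} not found in {path}")
        if column_spec.get(t, "numeric") != "numeric":
            raise ValueError(f"target column {t!r} must be declared numeric")
        if not pd.api.types.is_numeric_dtype(df[t]):
            raise ValueError(f"target column {t!r} is not numeric")
    spec = dict(column_spec)
    undeclared = tuple(c for c in df.columns if c not in spec and c not in targets)
    for c in undeclared:
        spec[c] = "identifier"
    for t in targets:
        spec.setdefault(t, "numeric")
    return FeatureTable(df=df, column_spec=spec, target_columns=targets,
                        undeclared_columns=undeclared)


def clean_table(table: FeatureTable,
                missing_policy: str = "impute_median") -> FeatureTable:
    """Deduplicate rows and resolve missing numeric cells.

    Exact duplicate rows keep their first occurrence. Missing values in
    numeric feature columns are median-imputed or their rows dropped,
    depending on policy; a missing target always drops the row. The
    operation is idempotent and records counts in ``clean_report``.
    """
    if missing_policy not in ("drop_row", "impute_median"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if table.n_rows == 0:
        raise ValueError("cannot clean an empty table")
    df = table.df.copy()
    before = len(df)
    df = df.drop_duplicates(keep="first").reset_index(drop=True)
    duplicates_removed = before - len(df)

    df = df.dropna(subset=list(table.target_columns)).reset_index(drop=True)

    numeric_cols = [c for c, k in table.column_spec.items()
                    if k == "numeric" and c in df.columns
                    and c not in table.target_columns]
    cells_imputed = 0
    rows_dropped = 0
    if missing_policy == "impute_median":
        for c in numeric_cols:
            n_missing = int(df[c].isna().sum())
            if n_missing:
                df[c] = df[c].fillna(df[c].median())
                cells_imputed += n_missing
    else:
        before = len(df)
        df = df.dropna(subset=numeric_cols).reset_index(drop=True)
        rows_dropped = before - len(df)
    if len(df) == 0:
        raise ValueError("cleaning removed every row")
    report = {"duplicates_removed": duplicates_removed,
              "cells_imputed": cells_imputed,
              "rows_dropped": rows_dropped,
              "missing_policy": missing_policy}
    return FeatureTable(df=df, column_spec=table.column_spec,
                        target_columns=table.target_columns,
                        undeclared_columns=table.undeclared_columns,
                        clean_report=report)


def _encode_column(s: pd.Series, kind: str) -> np.ndarray | None:
    if kind in ("text", "identifier"):
        return None
    if s.dtype == bool:
        return s.to_numpy().astype(np.float64)
    if kind == "categorical":
        labels = sorted(map(str, pd.unique(s.astype(str))))
        code = {lab: i for i, lab in enumerate(labels)}
        return np.array([code[str(v)] for v in s], dtype=np.float64)
    # numeric
    vals = pd.to_numeric(s)
    return vals.to_numpy(dtype=np.float64)


def encode_numeric(table: FeatureTable, standardize: bool = True,
                   ) -> tuple[FeatureMatrix, dict[str, ScoreVector], dict]:
    """Turn a cleaned table into a real matrix plus one ScoreVector per target.

    Returns (matrix, targets, log). The log records which columns were
    dropped (text/identifier), integer-coded, or removed as constant.
    """
    df = table.df
    kept: list[str] = []
    cols: list[np.ndarray] = []
    log: dict[str, list[str]] = {"dropped": [], "categorical_coded": [],
                                 "constant_removed": []}
    for name in df.columns:
        if name in table.target_columns:
            continue
        kind = table.column_spec.get(name, "identifier")
        enc = _encode_column(df[name], kind)
        if enc is None:
            log["dropped"].append(name)
            continue
        if kind == "categorical":
            log["categorical_coded"].append(name)
        if np.all(enc == enc[0]):
            log["constant_removed"].append(name)
            continue
        kept.append(name)
        cols.append(enc)
    if not cols:
        raise ValueError("no numeric feature columns survive encoding")
    X = np.column_stack(cols)
    matrix = FeatureMatrix(values=X, feature_names=kept,
                           sample_ids=list(df.index))
    if standardize:
        matrix = standardize_features(matrix)
    targets = {t: ScoreVector(df[t].to_numpy(dtype=np.float64), name=t)
               for t in table.target_columns}
    return matrix, targets, log


def standardize_features(X: FeatureMatrix,
                         means: np.ndarray | None = None,
                         sds: np.ndarray | None = None) -> FeatureMatrix:
    """Z-score columns; pass stored (means, sds) to transform held-out data."""
    if means is None:
        means = X.values.mean(axis=0)
        sds = X.values.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X.values - means) / sds
    return FeatureMatrix(values=Z, feature_names=list(X.feature_names),
                         sample_ids=list(X.sample_ids), standardized=True,
                         scale_means=np.asarray(means), scale_sds=np.asarray(sds))


def split_train_test(M: int, train_fraction: float, seed: int,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint exhaustive row partition; train size = round(f * M)."""
    if M < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * M))
    if n_train == 0 or n_train == M:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty side for M={M}")
    perm = np.random.default_rng(seed).permutation(M)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def take_rows(X: FeatureMatrix, idx: Iterable[int]) -> FeatureMatrix:
    idx = np.asarray(list(idx), dtype=int)
    return FeatureMatrix(values=X.values[idx],
                         feature_names=list(X.feature_names),
                         sample_ids=[X.sample_ids[i] for i in idx],
                         standardized=X.standardized,
                         scale_means=X.scale_means, scale_sds=X.scale_sds)
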