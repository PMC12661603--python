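"""Cohort containers and flat-file ingestion.

A cohort is a rectangular table of clinical features, one row per patient.
Columns are tagged ``numeric`` or ``categorical``; demographic columns are
carried alongside as metadata so they can feed subgroup reports without ever
entering distance computations or clustering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("coversample")

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass
class CohortMatrix:
    """Feature table over which distances, clusters and samples are defined.

    Parameters
    ----------
    data:
        Feature columns only, one row per patient.  Numeric columns are
        floats; categorical columns hold hashable level labels.
    feature_kinds:
        Mapping of column name to ``"numeric"`` or ``"categorical"``.
    row_ids:
        Stable unique identifiers, aligned with ``data`` rows.
    demographics:
        Optional columns excluded from distances/clustering but available to
        subgroup reports and balance tables.
    """

    data: pd.DataFrame
    feature_kinds: Mapping[str, str]
    row_ids: np.ndarray = None  # type: ignore[assignment]
    demographics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("cohort must have at least one row and one feature")
        unknown = set(self.data.columns) - set(self.feature_kinds)
        if unknown:
            raise ValueError(f"columns without a feature kind: {sorted(unknown)}")
        bad = {k: v for k, v in self.feature_kinds.items() if v not in (NUMERIC, CATEGORICAL)}
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")
        if self.data.isna().any().any():
            cols = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in feature columns {cols}; impute or drop before construction")
        if self.row_ids is None:
            self.row_ids = np.asarray(self.data.index)
        self.row_ids = np.asarray(self.row_ids)
        if len(self.row_ids) != len(self.data):
            raise ValueError("row_ids length does not match data")
        if len(np.unique(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.feature_kinds[c] == NUMERIC]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.feature_kinds[c] == CATEGORICAL]

    def numeric_values(self) -> np.ndarray:
        """Raw numeric feature matrix (no standardization)."""
        return self.data[self.numeric_columns].to_numpy(dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, column_prefix: str = "x") -> "CohortMatrix":
        """Wrap an all-numeric array; columns named ``x1..xp``."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        cols = [f"{column_prefix}{j + 1}" for j in range(values.shape[1])]
        df = pd.DataFrame(values, columns=cols)
        return cls(df, {c: NUMERIC for c in cols})


@dataclass(frozen=True)
class DistanceConfig:
    """Settings for pairwise distances and the coverage metric.

    ``n_lo .. n_hi`` is the range of nearest-neighbor orders averaged into the
    coverage score (the sample-selection criterion).  ``standardize`` z-scores
    numeric columns before euclidean/manhattan distances so that features on
    large scales do not dominate; Gower has its own range normalization.
    """

    metric: str = "euclidean"
    standardize: bool = True
    n_lo: int = 1
    n_hi: int = 10

    def __post_init__(self) -> None:
        if self.metric not in ("euclidean", "manhattan", "gower"):
            raise ValueError(f"unknown metric {self.metric!r}; expected euclidean, manhattan or gower")
        if not (1 <= self.n_lo <= self.n_hi):
            raise ValueError(f"need 1 <= n_lo <= n_hi, got n_lo={self.n_lo}, n_hi={self.n_hi}")


# ---------------------------------------------------------------------------
# ingestion / serialization
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Column roles and analysis settings for a cohort CSV.

    ``demographics`` columns are kept out of the feature set by construction;
    ``missing`` selects the ingestion policy for rows with missing feature
    values (``"error"`` rejects with row diagnostics, ``"impute"`` fills
    numeric columns with the mean and categorical ones with the mode).
    """

    id_column: str | None = None
    numeric_features: Sequence[str] = field(default_factory=list)
    categorical_features: Sequence[str] = field(default_factory=list)
    demographics: Sequence[str] = field(default_factory=list)
    outcome: str | None = None
    missing: str = "error"

    def __post_init__(self) -> None:
        feats = set(self.numeric_features) | set(self.categorical_features)
        overlap = feats & ({self.id_column, self.outcome} - {None})
        if overlap:
            raise ValueError(f"feature columns overlap id/outcome roles: {sorted(overlap)}")
        if set(self.numeric_features) & set(self.categorical_features):
            raise ValueError("a column cannot be both numeric and categorical")
        if self.missing not in ("error", "impute"):
            raise ValueError("missing policy must be 'error' or 'impute'")
        if not feats:
            raise ValueError("at least one feature column is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def load_cohort(path: str | Path, config: RunConfig) -> CohortMatrix:
    """Read a cohort CSV into a :class:`CohortMatrix` per the column roles.

    Raises on missing declared columns, non-numeric values in numeric columns
    and (under the ``error`` policy) rows with missing feature values.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    declared = list(config.numeric_features) + list(config.categorical_features)
    declared += [c for c in (config.id_column, config.outcome) if c]
    declared += list(config.demographics)
    absent = [c for c in declared if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: declared columns missing from header: {absent}")

    for col in config.numeric_features:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValueError(f"{path}: non-numeric values in numeric column {col!r} at rows {rows}")
        df[col] = coerced

    feat_cols = list(config.numeric_features) + list(config.categorical_features)
    na_mask = df[feat_cols].isna().any(axis=1)
    if na_mask.any():
        if config.missing == "error":
            rows = df.index[na_mask].tolist()[:10]
            raise ValueError(f"{path}: {int(na_mask.sum())} rows with missing feature values (e.g. rows {rows})")
        for col in config.numeric_features:
            df[col] = df[col].fillna(df[col].mean())
        for col in config.categorical_features:
            df[col] = df[col].fillna(df[col].mode().iloc[0])
        logger.info("imputed missing values in %d rows", int(na_mask.sum()))

    row_ids = df[config.id_column].to_numpy() if config.id_column else df.index.to_numpy()
    demo = df[list(config.demographics)].copy() if config.demographics else None
    kinds = {c: NUMERIC for c in config.numeric_features}
    kinds.update({c: CATEGORICAL for c in config.categorical_features})
    cohort = CohortMatrix(df[feat_cols].copy(), kinds, row_ids=row_ids, demographics=demo)
    if config.outcome:
        cohort.data.attrs["outcome"] = df[config.outcome].to_numpy()
    return cohort


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_selection(selection, cohort: CohortMatrix, path: str | Path) -> Path:
    """Write selected row ids as CSV plus a JSON provenance sidecar.

    The CSV holds the selected ``row_id`` values in stable (sorted-index)
    order; the sidecar records method, k, replicate, seed, the coverage
    metric value and a hash of the provenance block.  Returns the CSV path.
    """
    path = Path(path)
    ids = cohort.row_ids[np.asarray(selection.indices)]
    pd.DataFrame({"row_id": ids}).to_csv(path, index=False)
    prov = dict(selection.provenance)
    sidecar = {
        "provenance": prov,
        "metric_value": selection.metric_value,
        "m": int(len(selection.indices)),
        "config_hash": _config_hash(prov),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_selection_ids(path: str | Path) -> np.ndarray:
    """Read back the row ids written by :func:`write_selection`."""
    return pd.read_csv(path)["row_id"].to_numpy()
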