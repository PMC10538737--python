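"""Cohort tables: reading, validation, encoding and train/test splitting.

A cohort is a patient-by-feature table with a binary outcome. Features are
declared up front in a metadata config (kind, levels, reference level);
loading rejects anything the config does not describe rather than guessing.
Categorical features are dummy-coded against their reference level, binary
features become a single 0/1 column, continuous columns pass through
untouched. ``column_map`` remembers which encoded columns belong to which
clinical feature so downstream code (block permutation, feature subsetting)
can treat the clinical variable as the unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMeta",
    "CohortTable",
    "SplitSpec",
    "CohortError",
    "MissingOutcomeError",
    "UnknownLevelError",
    "NonNumericError",
    "read_cohort",
    "read_feature_config",
    "encode_features",
    "decode_feature",
    "split_data",
]


class CohortError(ValueError):
    """Base class for cohort loading/validation failures."""


class MissingOutcomeError(CohortError):
    """The declared outcome column is absent from the file."""


class UnknownLevelError(CohortError):
    """A categorical value not listed in the feature's declared levels."""


class NonNumericError(CohortError):
    """A non-numeric value in a column declared continuous."""


@dataclass(frozen=True)
class FeatureMeta:
    """Declared type of one clinical feature.

    Parameters
    ----------
    name
        Feature name, unique within a cohort.
    kind
        ``"binary"``, ``"categorical"`` or ``"continuous"``.
    levels
        Ordered level labels; exactly 2 for binary, >= 2 for categorical,
        ``None`` for continuous.
    reference_level
        Level encoded as 0 / baseline.  Defaults to the first level.
    """

    name: str
    kind: str
    levels: tuple | None = None
    reference_level: object = None

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "continuous"):
            raise CohortError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            if self.levels is not None:
                raise CohortError(f"continuous feature {self.name!r} must not declare levels")
            return
        if self.levels is None or len(self.levels) < 2:
            raise CohortError(f"feature {self.name!r} needs >= 2 levels")
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind == "binary" and len(self.levels) != 2:
            raise CohortError(f"binary feature {self.name!r} must have exactly 2 levels")
        if self.reference_level is None:
            object.__setattr__(self, "reference_level", self.levels[0])
        elif self.reference_level not in self.levels:
            raise CohortError(
                f"reference level {self.reference_level!r} of {self.name!r} not in levels"
            )


@dataclass
class CohortTable:
    """Encoded design matrix, binary outcome and feature bookkeeping."""

    X: np.ndarray
    Y: np.ndarray
    meta: list[FeatureMeta]
    column_map: dict[str, list[int]]
    encoded_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y)
        if self.X.ndim != 2 or self.X.shape[0] != self.Y.shape[0]:
            raise CohortError("X and Y row counts disagree")
        if not np.isfinite(self.X).all():
            raise CohortError("encoded matrix contains missing/non-finite values")
        if not np.isin(self.Y, (0, 1)).all():
            raise CohortError("outcome must be coded {0, 1}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    @property
    def continuous_columns(self) -> list[int]:
        """Encoded column indices of continuous features (for standardization)."""
        return [
            c for m in self.meta if m.kind == "continuous" for c in self.column_map[m.name]
        ]

    def has_both_classes(self) -> bool:
        return 0 < self.Y.sum() < self.n

    def subset_rows(self, idx: Sequence[int]) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(self.X[idx], self.Y[idx], self.meta, self.column_map,
                           self.encoded_names)

    def subset_features(self, names: Sequence[str]) -> "CohortTable":
        """Restrict to a subset of clinical features, re-indexing columns."""
        unknown = [f for f in names if f not in self.column_map]
        if unknown:
            raise CohortError(f"unknown features in subset: {unknown}")
        cols, new_map, new_names, new_meta = [], {}, [], []
        by_name = {m.name: m for m in self.meta}
        for f in names:
            start = len(cols)
            cols.extend(self.column_map[f])
            new_map[f] = list(range(start, len(cols)))
            new_names.extend(self.encoded_names[c] for c in self.column_map[f])
            new_meta.append(by_name[f])
        return CohortTable(self.X[:, cols], self.Y, new_meta, new_map, new_names)


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible train/test partition (indices, not copies)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    stratified: bool
    ratio: float | None = None

    def __post_init__(self):
        tr, te = np.asarray(self.train_idx), np.asarray(self.test_idx)
        if np.intersect1d(tr, te).size:
            raise CohortError("train/test overlap")
        if not np.array_equal(np.sort(np.concatenate([tr, te])),
                              np.arange(tr.size + te.size)):
            raise CohortError("split does not cover all rows exactly once")


def read_feature_config(path: str | Path) -> tuple[list[FeatureMeta], str, object]:
    """Read a YAML/JSON feature config.

    Expected keys: ``features`` (list of name/kind/levels/reference_level
    mappings), ``outcome_name`` and ``positive_label``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    metas = [
        FeatureMeta(
            name=f["name"], kind=f["kind"],
            levels=tuple(f["levels"]) if f.get("levels") else None,
            reference_level=f.get("reference_level"),
        )
        for f in cfg["features"]
    ]
    return metas, cfg["outcome_name"], cfg["positive_label"]


def encode_features(
    raw: pd.DataFrame, meta: Sequence[FeatureMeta]
) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """Numerically encode a raw feature frame.

    Binary -> one 0/1 column (reference level 0); categorical with k levels
    -> k-1 indicators against the reference level; continuous unchanged.
    """
    names = [m.name for m in meta]
    if len(set(names)) != len(names):
        raise CohortError("duplicate feature names in metadata")
    cols: list[np.ndarray] = []
    column_map: dict[str, list[int]] = {}
    encoded_names: list[str] = []
    for m in meta:
        if m.name not in raw.columns:
            raise CohortError(f"feature {m.name!r} missing from table")
        v = raw[m.name]
        start = len(cols)
        if m.kind == "continuous":
            arr = pd.to_numeric(v, errors="coerce").to_numpy(dtype=float)
            bad = np.isnan(arr) & ~pd.isna(v).to_numpy()
            if bad.any():
                raise NonNumericError(
                    f"non-numeric value {v[bad].iloc[0]!r} in continuous feature {m.name!r}"
                )
            cols.append(arr)
            encoded_names.append(m.name)
        else:
            vals = v.to_numpy()
            known = set(m.levels)
            unseen = [x for x in pd.unique(v.dropna()) if x not in known]
            if unseen:
                raise UnknownLevelError(
                    f"unknown level {unseen[0]!r} in feature {m.name!r} "
                    f"(declared levels: {list(m.levels)})"
                )
            non_ref = [lv for lv in m.levels if lv != m.reference_level]
            if m.kind == "binary":
                non_ref = non_ref[:1]
            for lv in non_ref:
                cols.append((vals == lv).astype(float))
                encoded_names.append(f"{m.name}={lv}" if m.kind == "categorical" else m.name)
        column_map[m.name] = list(range(start, len(cols)))
    X = np.column_stack(cols) if cols else np.empty((len(raw), 0))
    return X, column_map, encoded_names


def decode_feature(table: CohortTable, name: str) -> np.ndarray:
    """Recover original level labels of an encoded binary/categorical feature."""
    m = next(mm for mm in table.meta if mm.name == name)
    if m.kind == "continuous":
        return table.X[:, table.column_map[name][0]]
    non_ref = [lv for lv in m.levels if lv != m.reference_level]
    if m.kind == "binary":
        non_ref = non_ref[:1]
    block = table.X[:, table.column_map[name]]
    out = np.full(table.n, m.reference_level, dtype=object)
    for k, lv in enumerate(non_ref):
        out[block[:, k] == 1.0] = lv
    return out


def read_cohort(
    path: str | Path,
    meta: Sequence[FeatureMeta],
    outcome_name: str,
    positive_label: object,
    sheet: int | str = 0,
) -> CohortTable:
    """Load a CSV/XLSX patient table and return an encoded :class:`CohortTable`.

    Rows with missing values in any declared column are rejected with a
    logged warning (no imputation).  The outcome is mapped so that
    ``positive_label`` becomes 1.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path)
    if outcome_name not in raw.columns:
        raise MissingOutcomeError(
            f"outcome column {outcome_name!r} not found in {path.name} "
            f"(columns: {list(raw.columns)[:8]}...)"
        )
    used = [m.name for m in meta] + [outcome_name]
    missing_cols = [c for c in used if c not in raw.columns]
    if missing_cols:
        raise CohortError(f"columns missing from {path.name}: {missing_cols}")
    sub = raw[used]
    keep = ~sub.isna().any(axis=1)
    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.warning("%s: rejected %d rows with missing values", path.name, n_rejected)
    sub = sub.loc[keep]
    outcome_vals = pd.unique(sub[outcome_name])
    if len(outcome_vals) > 2:
        raise CohortError(f"outcome {outcome_name!r} has >2 distinct values: {outcome_vals}")
    if positive_label not in outcome_vals and len(outcome_vals) == 2:
        raise CohortError(
            f"positive label {positive_label!r} not among outcome values {outcome_vals}"
        )
    Y = (sub[outcome_name] == positive_label).astype(int).to_numpy()
    X, column_map, encoded_names = encode_features(sub.drop(columns=[outcome_name]), meta)
    table = CohortTable(X, Y, list(meta), column_map, encoded_names)
    logger.info(
        "%s: loaded n=%d rows (%d rejected), %d features -> %d encoded columns, "
        "%d positive outcomes", path.name, table.n, n_rejected, len(meta),
        X.shape[1], int(Y.sum()),
    )
    if not table.has_both_classes():
        logger.warning("%s: outcome has a single class; table unusable for fitting", path.name)
    return table


def split_data(
    cohort: CohortTable,
    *,
    ratio: float | None = None,
    test_n: int | None = None,
    seed: int = 0,
    stratified: bool = False,
) -> SplitSpec:
    """Deterministic train/test split.

    ``ratio`` is the target train:test ratio (e.g. 10 for 10:1); ``test_n``
    pins the test-set size exactly and overrides ``ratio``.  Uses numpy's
    PCG64 generator, so a fixed seed reproduces the split on any platform.
    """
    n = cohort.n
    if n < 2:
        raise CohortError("need at least 2 rows to split")
    if test_n is None:
        if ratio is None:
            raise CohortError("provide ratio or test_n")
        test_n = int(round(n / (ratio + 1.0)))
    if not 0 < test_n < n:
        raise CohortError(f"test size {test_n} invalid for n={n}")
    rng = np.random.default_rng(seed)
    if stratified:
        test_parts = []
        # largest-remainder allocation of test_n across classes
        classes, counts = np.unique(cohort.Y, return_counts=True)
        quotas = test_n * counts / n
        base = np.floor(quotas).astype(int)
        rem = test_n - base.sum()
        order = np.argsort(-(quotas - base))
        base[order[:rem]] += 1
        for cls, k in zip(classes, base):
            rows = np.flatnonzero(cohort.Y == cls)
            test_parts.append(rng.permutation(rows)[:k])
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        test_idx = np.sort(rng.permutation(n)[:test_n])
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return SplitSpec(train_idx=train_idx, test_idx=test_idx, seed=seed,
                     stratified=stratified, ratio=ratio)
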