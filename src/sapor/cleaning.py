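"""Feature-table cleaning rules and per-model-family preprocessing.

Structural cleaning (applied once to the assembled table, in this order):

1. duplicate rows — identical feature rows with agreeing targets keep one
   representative, conflicting targets are removed entirely;
2. columns with >= 95% missing values are dropped;
3. near-constant columns (one value covering >= 99% of non-missing entries,
   or fully constant) are dropped;
4. entrywise-identical columns are collapsed to a single representative.

Statistical preprocessing (fitted on CV training folds only): 90%
winsorization (clip at the 5th/95th percentile), optional min-max scaling,
and constant out-of-distribution imputation of the missing-not-at-random
values (1 for models needing a bounded scale, -99999 for the random forest,
or native missing for learners that route NaN themselves).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import FeatureTable

__all__ = [
    "CleaningReport",
    "PreprocessPolicy",
    "NATIVE_MISSING",
    "resolve_duplicate_rows",
    "drop_high_missing",
    "drop_near_constant",
    "collapse_duplicate_columns",
    "clean_table",
    "Winsorizer",
    "winsorize",
    "minmax_scale",
    "impute_mnar",
]

#: sentinel for "leave NaN in place; the learner handles missing natively"
NATIVE_MISSING = "native_missing"


@dataclass
class CleaningReport:
    n_rows_in: int = 0
    n_rows_out: int = 0
    n_cols_in: int = 0
    n_cols_out: int = 0
    dropped_high_missing: list[str] = field(default_factory=list)
    dropped_near_constant: list[str] = field(default_factory=list)
    collapsed_duplicate_columns: list[list[str]] = field(default_factory=list)
    removed_conflicting_rows: list[str] = field(default_factory=list)
    collapsed_duplicate_rows: int = 0

    def validate(self) -> None:
        """Column arithmetic must account for every dropped/collapsed column."""
        collapsed = sum(len(g) - 1 for g in self.collapsed_duplicate_columns)
        expected = (
            self.n_cols_in
            - len(self.dropped_high_missing)
            - len(self.dropped_near_constant)
            - collapsed
        )
        if self.n_cols_out != expected:
            raise AssertionError(
                f"column arithmetic mismatch: out={self.n_cols_out}, expected={expected}"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class PreprocessPolicy:
    """Per-model-family preprocessing: winsorize percentiles, scaling, imputation."""

    winsorize_lo: float = 5.0
    winsorize_hi: float = 95.0
    scale: str = "none"  # {"minmax", "none"}
    impute_constant: float | str = NATIVE_MISSING

    def __post_init__(self) -> None:
        if not (0 < self.winsorize_lo < self.winsorize_hi < 100):
            raise ValueError("require 0 < winsorize_lo < winsorize_hi < 100")
        if self.scale not in ("minmax", "none"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.impute_constant != NATIVE_MISSING and not np.isfinite(self.impute_constant):
            raise ValueError("impute_constant must be finite or native_missing")


def resolve_duplicate_rows(table: FeatureTable) -> tuple[FeatureTable, CleaningReport]:
    """Keep one row per identical-feature group; drop target-conflicting groups."""
    rep = CleaningReport(
        n_rows_in=table.n_rows, n_cols_in=table.n_cols,
        n_cols_out=table.n_cols,
    )
    X, y = table.X, table.y
    # NaN == NaN for the purpose of row identity (pandas duplicated semantics)
    grouped: dict[tuple, list] = {}
    arr = X.to_numpy()
    for pos in range(len(X)):
        key = arr[pos].tobytes()
        grouped.setdefault(key, []).append(pos)
    keep_pos: list[int] = []
    for _, positions in grouped.items():
        targets = {int(y.iloc[p]) for p in positions}
        if len(targets) == 1:
            keep_pos.append(positions[0])
            rep.collapsed_duplicate_rows += len(positions) - 1
        else:
            rep.removed_conflicting_rows.extend(str(X.index[p]) for p in positions)
    keep_pos.sort()
    out = FeatureTable(X.iloc[keep_pos].copy(), y.iloc[keep_pos].copy(), dict(table.source_tags))
    rep.n_rows_out = out.n_rows
    return out, rep


def drop_high_missing(
    table: FeatureTable, threshold: float = 0.95
) -> tuple[FeatureTable, CleaningReport]:
    """Drop columns whose missing fraction is >= ``threshold`` (note: >=, not >)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    mf = table.missing_fraction()
    dropped = list(mf.index[mf >= threshold])
    keep = [c for c in table.X.columns if c not in set(dropped)]
    out = table.subset_columns(keep)
    rep = CleaningReport(
        n_rows_in=table.n_rows, n_rows_out=out.n_rows,
        n_cols_in=table.n_cols, n_cols_out=out.n_cols,
        dropped_high_missing=dropped,
    )
    return out, rep


def drop_near_constant(
    table: FeatureTable, dominance: float = 0.99
) -> tuple[FeatureTable, CleaningReport]:
    """Drop columns whose modal non-missing value covers >= ``dominance`` of
    non-missing entries, and constant (or all-missing) columns."""
    if not (0 < dominance <= 1):
        raise ValueError("dominance must be in (0, 1]")
    dropped = []
    for c in table.X.columns:
        col = table.X[c].dropna()
        if len(col) == 0:
            dropped.append(c)  # nothing observed: carries no signal
            continue
        top = col.value_counts().iloc[0]
        if col.nunique() == 1 or top / len(col) >= dominance:
            dropped.append(c)
    keep = [c for c in table.X.columns if c not in set(dropped)]
    out = table.subset_columns(keep)
    rep = CleaningReport(
        n_rows_in=table.n_rows, n_rows_out=out.n_rows,
        n_cols_in=table.n_cols, n_cols_out=out.n_cols,
        dropped_near_constant=dropped,
    )
    return out, rep


def collapse_duplicate_columns(table: FeatureTable) -> tuple[FeatureTable, CleaningReport]:
    """Collapse entrywise-identical columns (missing matches missing) to the
    lexicographically-first name of each group."""
    groups: dict[bytes, list[str]] = {}
    for c in table.X.columns:
        key = table.X[c].to_numpy().tobytes()
        groups.setdefault(key, []).append(c)
    collapsed_groups = []
    drop: set[str] = set()
    for names in groups.values():
        if len(names) > 1:
            names_sorted = sorted(names)
            collapsed_groups.append(names_sorted)
            drop.update(names_sorted[1:])
    keep = [c for c in table.X.columns if c not in drop]
    out = table.subset_columns(keep)
    rep = CleaningReport(
        n_rows_in=table.n_rows, n_rows_out=out.n_rows,
        n_cols_in=table.n_cols, n_cols_out=out.n_cols,
        collapsed_duplicate_columns=collapsed_groups,
    )
    return out, rep


def clean_table(
    table: FeatureTable,
    missing_threshold: float = 0.95,
    dominance: float = 0.99,
) -> tuple[FeatureTable, CleaningReport]:
    """Full structural cleaning: duplicate rows, high-missing columns,
    near-constant columns, duplicate columns — in that order."""
    t1, r1 = resolve_duplicate_rows(table)
    t2, r2 = drop_high_missing(t1, threshold=missing_threshold)
    t3, r3 = drop_near_constant(t2, dominance=dominance)
    t4, r4 = collapse_duplicate_columns(t3)
    rep = CleaningReport(
        n_rows_in=table.n_rows,
        n_rows_out=t4.n_rows,
        n_cols_in=table.n_cols,
        n_cols_out=t4.n_cols,
        dropped_high_missing=r2.dropped_high_missing,
        dropped_near_constant=r3.dropped_near_constant,
        collapsed_duplicate_columns=r4.collapsed_duplicate_columns,
        removed_conflicting_rows=r1.removed_conflicting_rows,
        collapsed_duplicate_rows=r1.collapsed_duplicate_rows,
    )
    rep.validate()
    return t4, rep


class Winsorizer(BaseEstimator, TransformerMixin):
    """Clip each column at percentiles fitted on the training data.

    Percentiles use the linear-interpolation convention.  Missing values
    pass through untouched; applying the fitted bounds is idempotent.  A
    column that is entirely missing in the training data raises.
    """

    def __init__(self, lo: float = 5.0, hi: float = 95.0):
        self.lo = lo
        self.hi = hi

    def fit(self, X, y=None):
        if not (0 < self.lo < self.hi < 100):
            raise ValueError("require 0 < lo < hi < 100")
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        n_obs = np.sum(~np.isnan(arr), axis=0)
        if np.any(n_obs < 2):
            bad = np.where(n_obs < 2)[0]
            raise ValueError(
                f"winsorization needs >= 2 non-missing training values; "
                f"columns at positions {bad.tolist()} have fewer"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.lower_, self.upper_ = np.nanpercentile(
                arr, [self.lo, self.hi], axis=0, method="linear"
            )
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "lower_")
        arr = np.asarray(X, dtype=float)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr.reshape(-1, 1)
        out = np.clip(arr, self.lower_, self.upper_)  # NaN propagates unchanged
        out = np.where(np.isnan(arr), np.nan, out)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out[:, 0] if squeeze else out


def winsorize(
    column, lo: float = 5.0, hi: float = 95.0, fitted_on=None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Clip one column into its [p_lo, p_hi] band; bounds fitted on
    ``fitted_on`` (training values) when given, else on the column itself."""
    w = Winsorizer(lo=lo, hi=hi)
    train = column if fitted_on is None else fitted_on
    w.fit(np.asarray(train, dtype=float).reshape(-1, 1))
    out = w.transform(np.asarray(column, dtype=float).reshape(-1, 1))[:, 0]
    return out, (float(w.lower_[0]), float(w.upper_[0]))


def minmax_scale(column, fitted_on=None) -> tuple[np.ndarray, tuple[float, float]]:
    """Scale so training values span [0, 1]; held-out values may exceed the
    band and are not re-clipped; missing passes through.  Zero range raises."""
    col = np.asarray(column, dtype=float)
    train = col if fitted_on is None else np.asarray(fitted_on, dtype=float)
    mn, mx = np.nanmin(train), np.nanmax(train)
    if not np.isfinite(mn) or mx - mn == 0:
        raise ValueError("zero range: constant column should have been dropped")
    return (col - mn) / (mx - mn), (float(mn), float(mx))


def impute_mnar(table: FeatureTable, policy: PreprocessPolicy) -> FeatureTable:
    """Replace missing cells with the policy constant, or pass the table
    through unchanged under the native-missing policy."""
    if policy.impute_constant == NATIVE_MISSING:
        return table
    out = table.copy()
    out.X = out.X.fillna(float(policy.impute_constant))
    return out
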