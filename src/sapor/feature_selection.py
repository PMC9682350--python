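"""Correlation-cluster / KS-test sequential feature selection.

The selection algorithm picks a small set of informative, mutually weakly
correlated descriptors in three steps:

(i)   rank every feature by its univariate class separation, measured with
      the two-sample Kolmogorov–Smirnov statistic between the bitter and
      sweet value distributions;
(ii)  cluster the features by Ward hierarchical agglomeration on the
      distance ``1 - |Spearman rho|``, so strongly (anti-)correlated
      features land in the same cluster;
(iii) cut the merge tree at k clusters and keep one representative per
      cluster — the member with the largest KS statistic — then score the
      k-feature set with stratified cross-validation of a reference
      learner, sweeping k from 1 to the number of features.

The merge tree is computed once and cut repeatedly, so the sweep costs one
clustering plus one small CV run per k.  Missing values are dropped
pairwise in both the KS and the Spearman computation: the constant
imputation values used for modelling would fabricate rank structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import FeatureTable
from .modeling import CVSpec, ModelSpec, run_cv

__all__ = [
    "FeatureRanking",
    "CorrelationStructure",
    "SelectionTrace",
    "ks_statistic",
    "rank_features",
    "spearman_matrix",
    "build_correlation_structure",
    "ward_clusters",
    "select_representatives",
    "intra_cluster_mean_abs_corr",
    "KSClusterSelector",
    "sequential_sweep",
    "choose_k",
]


@dataclass
class FeatureRanking:
    """Per-feature two-sample KS statistic and p-value."""

    table: pd.DataFrame  # index: feature name; columns: ks_stat, ks_p

    def statistic(self, name: str) -> float:
        return float(self.table.loc[name, "ks_stat"])

    def best(self) -> str:
        """Feature with the largest KS statistic; ties broken by name."""
        t = self.table.sort_index()
        return str(t["ks_stat"].idxmax())


@dataclass
class CorrelationStructure:
    """Spearman matrix, derived distance and cached Ward merge tree."""

    matrix: pd.DataFrame
    distance: np.ndarray  # condensed form
    linkage: np.ndarray
    sign: str = "abs"  # distance = 1 - |rho| ("abs") or 1 - rho ("signed")

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)


def ks_statistic(x, y) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_x - ECDF_y| with asymptotic p.

    Missing values are dropped; an empty sample after dropping raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS statistic needs non-empty samples in both classes")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def rank_features(table: FeatureTable) -> FeatureRanking:
    """KS class-separation score for every feature column.

    A feature with no observed values in one class cannot separate the
    classes; it is scored D=0, p=1 with a warning rather than dropped, so
    every clustered feature keeps a ranking entry.
    """
    y = table.y.to_numpy()
    rows = {}
    degenerate = []
    for c in table.X.columns:
        v = table.X[c].to_numpy(dtype=float)
        x0, x1 = v[y == 0], v[y == 1]
        x0, x1 = x0[~np.isnan(x0)], x1[~np.isnan(x1)]
        if len(x0) == 0 or len(x1) == 0:
            degenerate.append(c)
            rows[c] = (0.0, 1.0)
        else:
            res = stats.ks_2samp(x0, x1, alternative="two-sided", method="asymp")
            rows[c] = (float(res.statistic), float(res.pvalue))
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} feature(s) had no observed values in one class; "
            "scored as D=0"
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["ks_stat", "ks_p"])
    return FeatureRanking(df)


def spearman_matrix(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlation with average-rank ties.

    Pairs undefined after pairwise deletion (a side constant or too few
    joint observations) are set to 0 with a warning; the diagonal is 1.
    """
    X = table.X if isinstance(table, FeatureTable) else table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = X.corr(method="spearman")
    if rho.isna().to_numpy().any():
        n_bad = int(rho.isna().to_numpy().sum())
        warnings.warn(f"{n_bad} undefined correlation pair(s) set to 0")
        rho = rho.fillna(0.0)
    np.fill_diagonal(rho.values, 1.0)
    return rho.clip(-1.0, 1.0)


def build_correlation_structure(
    table: FeatureTable | pd.DataFrame, sign: str = "abs"
) -> CorrelationStructure:
    """Spearman matrix -> distance -> Ward merge tree (computed once)."""
    if sign not in ("abs", "signed"):
        raise ValueError("sign must be 'abs' or 'signed'")
    rho = spearman_matrix(table)
    d = 1.0 - (rho.abs() if sign == "abs" else rho)
    dm = d.to_numpy(dtype=float)
    dm = np.maximum((dm + dm.T) / 2.0, 0.0)
    np.fill_diagonal(dm, 0.0)
    condensed = squareform(dm, checks=False)
    Z = linkage(condensed, method="ward")
    return CorrelationStructure(matrix=rho, distance=condensed, linkage=Z, sign=sign)


def ward_clusters(structure: CorrelationStructure, n_clusters: int) -> pd.Series:
    """Cut the cached Ward tree at ``n_clusters``; returns name -> label."""
    names = structure.feature_names
    if not (1 <= n_clusters <= len(names)):
        raise ValueError(f"n_clusters must be in [1, {len(names)}]")
    labels = fcluster(structure.linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=names, name="cluster")


def select_representatives(assignment: pd.Series, ranking: FeatureRanking) -> list[str]:
    """One feature per cluster: the largest KS statistic, ties by name."""
    missing = set(assignment.index) - set(ranking.table.index)
    if missing:
        raise KeyError(f"no ranking entry for features: {sorted(missing)[:5]}")
    reps = []
    for _, members in assignment.groupby(assignment):
        names = sorted(members.index)
        ks = ranking.table.loc[names, "ks_stat"]
        reps.append(str(ks.idxmax()))  # idxmax takes the first on ties = lexicographic
    return sorted(reps)


def intra_cluster_mean_abs_corr(
    assignment: pd.Series, structure: CorrelationStructure
) -> float:
    """Mean |rho| over all within-cluster pairs; all-singleton -> 0."""
    rho = structure.matrix.abs()
    vals = []
    for _, members in assignment.groupby(assignment):
        names = list(members.index)
        m = len(names)
        if m < 2:
            continue
        sub = rho.loc[names, names].to_numpy()
        iu = np.triu_indices(m, k=1)
        vals.extend(sub[iu].tolist())
    return float(np.mean(vals)) if vals else 0.0


class KSClusterSelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer running steps (i)-(iii) at a fixed k.

    Fit computes the KS ranking, the Spearman/Ward structure and the
    representative set on the training data only, so the selector can sit
    inside a CV pipeline for a leakage-safe variant of the sweep.
    """

    def __init__(self, n_clusters: int = 2, sign: str = "abs"):
        self.n_clusters = n_clusters
        self.sign = sign

    def fit(self, X, y):
        X = self._as_frame(X)
        table = FeatureTable(X, pd.Series(np.asarray(y), index=X.index))
        self.ranking_ = rank_features(table)
        self.structure_ = build_correlation_structure(table, sign=self.sign)
        if self.n_clusters == 1:
            self.selected_features_ = [self.ranking_.best()]
            self.assignment_ = pd.Series(1, index=X.columns)
        else:
            self.assignment_ = ward_clusters(self.structure_, self.n_clusters)
            self.selected_features_ = select_representatives(self.assignment_, self.ranking_)
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        X = self._as_frame(X)
        return X[self.selected_features_]

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        width = len(str(X.shape[1] - 1))
        return pd.DataFrame(X, columns=[f"f{i:0{width}d}" for i in range(X.shape[1])])


@dataclass
class SelectionTrace:
    """Per-cluster-count record of the sweep: features, CV AUROC, intra-|rho|."""

    entries: list[dict] = field(default_factory=list)

    def add(self, k: int, features: list[str], cv_auroc: float, intra_corr: float) -> None:
        if len(features) != k:
            raise ValueError(f"entry at k={k} must have exactly {k} features")
        self.entries.append(
            {"k": k, "selected_features": list(features),
             "cv_auroc": float(cv_auroc),
             "mean_intra_cluster_abs_corr": float(intra_corr)}
        )

    def ks(self) -> list[int]:
        return [e["k"] for e in self.entries]

    def entry(self, k: int) -> dict:
        for e in self.entries:
            if e["k"] == k:
                return e
        raise KeyError(f"no trace entry at k={k}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries)
        df["selected_features"] = df["selected_features"].map(";".join)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sequential_sweep(
    table: FeatureTable,
    model: ModelSpec | None = None,
    cv: CVSpec | None = None,
    k_grid: list[int] | None = None,
    sign: str = "abs",
) -> SelectionTrace:
    """Sweep the cluster count k, scoring each representative set with CV.

    k=1 uses the single best-KS feature; k>=2 cuts the (cached) Ward tree.
    The reference learner defaults to gradient boosting under stratified
    5-fold CV; ``k_grid`` restricts the sweep for desk-scale runs (the full
    grid is 1..n_features).  Rankings and clusters are computed once on the
    whole table; for a leakage-safe per-fold variant embed
    :class:`KSClusterSelector` in a CV pipeline instead.
    """
    model = model or ModelSpec("gradient_boosting")
    cv = cv or CVSpec(k=5, repeats=1, seed=0)
    n_feat = table.n_cols
    if k_grid is None:
        k_grid = list(range(1, n_feat + 1))
    if any(k < 1 or k > n_feat for k in k_grid):
        raise ValueError(f"k_grid values must lie in [1, {n_feat}]")

    ranking = rank_features(table)
    structure = build_correlation_structure(table, sign=sign)
    trace = SelectionTrace()
    for k in sorted(set(k_grid)):
        if k == 1:
            feats = [ranking.best()]
            intra = 0.0
        else:
            assignment = ward_clusters(structure, k)
            feats = select_representatives(assignment, ranking)
            intra = intra_cluster_mean_abs_corr(assignment, structure)
        res = run_cv(table.subset_columns(feats), model, cv)
        trace.add(k, feats, res.per_fold["auroc"].mean(), intra)
    return trace


def choose_k(
    trace: SelectionTrace,
    strategy: str = "fixed_k",
    k: int = 29,
    tolerance: float = 0.01,
) -> list[str]:
    """Pick the working feature set from a sweep trace.

    ``fixed_k`` returns the entry at k (default 29, the compromise between
    performance and interpretability).  ``knee`` returns the smallest k whose
    AUROC is within ``tolerance`` of the largest-k (reference) AUROC.
    """
    if not trace.entries:
        raise ValueError("empty trace")
    if strategy == "fixed_k":
        return list(trace.entry(k)["selected_features"])
    if strategy == "knee":
        ref = trace.entry(max(trace.ks()))["cv_auroc"]
        for e in sorted(trace.entries, key=lambda e: e["k"]):
            if e["cv_auroc"] >= ref - tolerance:
                return list(e["selected_features"])
        raise RuntimeError("unreachable: reference entry satisfies its own tolerance")
    raise ValueError(f"unknown strategy {strategy!r}")
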