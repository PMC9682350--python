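"""Shapley-value attribution for the taste classifier.

The prediction for a molecule is decomposed additively,

    y_hat = y_base + phi_1 + phi_2 + ... + phi_M,

where ``y_base`` is the expected model output over a background sample of
training compounds and ``phi_j`` is the Shapley value of feature j: the
weighted average over all subsets S not containing j of
``|S|! (M-|S|-1)! / M! * [f_x(S + {j}) - f_x(S)]``.  The coalition value
``f_x(S)`` is the *interventional* expectation — model output with the
features in S fixed at the explained row and the remainder drawn from the
background — since the observational conditional is not computable without
a density model.  Positive phi pushes the prediction toward sweet (class 1),
negative toward bitter (class 0).

Two independent routes are provided:

* :func:`exact_shapley` — direct subset enumeration for any prediction
  function, feasible up to ~20 features; the reference oracle.
* :class:`TreeExplainer` — a polynomial closed form for tree ensembles.
  For one background row z, a leaf is reached under coalition S iff every
  split feature on its path where z takes the other branch is in S (set R)
  and every feature where x takes the other branch is outside S (set F);
  features whose x and z values both satisfy the path are irrelevant.  The
  leaf's Shapley contribution then reduces to a binomial sum over the count
  of included irrelevant features, so the cost is (leaves x path length)
  per background row rather than 2^M.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ShapExplanation",
    "ShapMatrix",
    "GlobalImportance",
    "exact_shapley",
    "TreeExplainer",
    "tree_shap_matrix",
    "global_importance",
    "summary_data",
    "dependence_data",
    "local_profile",
]

ENUMERATION_LIMIT = 20


@dataclass
class ShapExplanation:
    """Additive attribution of one prediction: base + sum(phi) = prediction."""

    base_value: float
    phi: pd.Series
    prediction: float
    feature_values: pd.Series

    def __post_init__(self) -> None:
        gap = abs(self.base_value + float(self.phi.sum()) - self.prediction)
        if gap > 1e-6:
            raise AssertionError(f"additivity violated: |base + sum(phi) - pred| = {gap:.3g}")


@dataclass
class ShapMatrix:
    """Per-compound phi vectors (rows) over features (columns)."""

    phi: pd.DataFrame
    base_value: float
    predictions: pd.Series
    background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        resid = (self.base_value + self.phi.sum(axis=1) - self.predictions).abs()
        if (resid > 1e-6).any():
            raise AssertionError(
                f"additivity violated on {int((resid > 1e-6).sum())} row(s); "
                f"max residual {resid.max():.3g}"
            )

    def explanation(self, row_id) -> ShapExplanation:
        return ShapExplanation(
            base_value=self.base_value,
            phi=self.phi.loc[row_id],
            prediction=float(self.predictions.loc[row_id]),
            feature_values=pd.Series(dtype=float),
        )

    def to_csv(self, path) -> None:
        out = self.phi.copy()
        out["base_value"] = self.base_value
        out["prediction"] = self.predictions
        out.to_csv(path, index_label="id")


@dataclass
class GlobalImportance:
    """Mean |phi| per feature, descending (ties broken by name)."""

    table: pd.DataFrame  # index: feature; column: importance

    def top(self, n: int) -> list[str]:
        return list(self.table.index[:n])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def _subset_weights(M: int) -> np.ndarray:
    """w[s] = s! (M-s-1)! / M! for s = 0..M-1."""
    return np.array(
        [math.factorial(s) * math.factorial(M - s - 1) / math.factorial(M) for s in range(M)]
    )


def exact_shapley(predict, x, background, enumeration_limit: int = ENUMERATION_LIMIT):
    """Exact Shapley values by subset enumeration (reference oracle).

    ``predict`` maps an (n, M) array to n outputs; ``x`` is the explained
    row; ``background`` the reference rows for the interventional
    expectation.  Returns ``(phi, base)`` with base = mean prediction over
    the background.  Cost is 2^M coalition evaluations; M above
    ``enumeration_limit`` raises (use :class:`TreeExplainer` instead).
    """
    x = np.asarray(x, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    M = x.size
    if M > enumeration_limit:
        raise ValueError(
            f"{M} features exceed the enumeration bound {enumeration_limit}; "
            "use the tree-path explainer for larger models"
        )
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    n_bg = bg.shape[0]

    # one stacked predict call: all 2^M coalitions x n_bg hybrid rows
    subsets = []
    for size in range(M + 1):
        subsets.extend(combinations(range(M), size))
    hybrids = np.repeat(bg[None, :, :], len(subsets), axis=0)  # (2^M, n_bg, M)
    for i, S in enumerate(subsets):
        if S:
            hybrids[i, :, list(S)] = x[list(S)][:, None]
    flat = hybrids.reshape(-1, M)
    v = np.asarray(predict(flat), dtype=float).reshape(len(subsets), n_bg).mean(axis=1)
    v_of = {S: v[i] for i, S in enumerate(subsets)}

    w = _subset_weights(M)
    phi = np.zeros(M)
    for j in range(M):
        others = [i for i in range(M) if i != j]
        for size in range(M):
            for S in combinations(others, size):
                phi[j] += w[size] * (v_of[tuple(sorted(S + (j,)))] - v_of[S])
    base = v_of[()]
    return phi, float(base)


# ---------------------------------------------------------------------------
# tree extraction: a neutral array form shared by sklearn and LightGBM models
# ---------------------------------------------------------------------------


@dataclass
class _Tree:
    feature: np.ndarray        # split feature per node, -1 for leaves
    threshold: np.ndarray
    left: np.ndarray           # child indices, -1 for leaves
    right: np.ndarray
    value: np.ndarray          # leaf value per node (internal nodes unused)
    default_left: np.ndarray   # NaN routing per node


@dataclass
class _Ensemble:
    trees: list[_Tree]
    weights: list[float]       # multiplier per tree (e.g. 1/n_trees, learning rate)
    offset: float = 0.0        # additive constant (init estimator); enters base only


def _from_sklearn_tree(t, scale: float) -> _Tree:
    return _Tree(
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        left=t.children_left.copy(),
        right=t.children_right.copy(),
        value=t.value[:, 0, 0] * scale if t.value.ndim == 3 else t.value.ravel() * scale,
        default_left=np.ones(t.node_count, dtype=bool),
    )


def _from_lightgbm(booster) -> _Ensemble:
    dump = booster.dump_model()
    trees = []
    for td in dump["tree_info"]:
        nodes: list[dict] = []

        def walk(nd) -> int:
            idx = len(nodes)
            nodes.append({})
            if "leaf_value" in nd and "split_feature" not in nd:
                nodes[idx] = {"feature": -1, "threshold": 0.0, "left": -1, "right": -1,
                              "value": nd["leaf_value"], "default_left": True}
            else:
                rec = {"feature": nd["split_feature"], "threshold": nd["threshold"],
                       "value": 0.0, "default_left": bool(nd.get("default_left", True))}
                nodes[idx] = rec
                rec["left"] = walk(nd["left_child"])
                rec["right"] = walk(nd["right_child"])
            return idx

        walk(td["tree_structure"])
        trees.append(
            _Tree(
                feature=np.array([n["feature"] for n in nodes]),
                threshold=np.array([n["threshold"] for n in nodes]),
                left=np.array([n["left"] for n in nodes]),
                right=np.array([n["right"] for n in nodes]),
                value=np.array([n["value"] for n in nodes]),
                default_left=np.array([n["default_left"] for n in nodes]),
            )
        )
    return _Ensemble(trees=trees, weights=[1.0] * len(trees), offset=0.0)


def _extract_ensemble(model) -> _Ensemble:
    """Neutral tree arrays from a fitted sklearn or LightGBM tree model."""
    name = type(model).__name__
    if hasattr(model, "booster_"):  # LGBMRegressor / LGBMClassifier
        return _from_lightgbm(model.booster_)
    if name == "Booster" and hasattr(model, "dump_model"):
        return _from_lightgbm(model)
    if hasattr(model, "tree_"):  # single decision tree (regressor)
        return _Ensemble([_from_sklearn_tree(model.tree_, 1.0)], [1.0], 0.0)
    if hasattr(model, "estimators_"):
        ests = model.estimators_
        if name == "GradientBoostingRegressor":
            lr = model.learning_rate
            trees = [_from_sklearn_tree(e.tree_, lr) for e in np.ravel(ests)]
            offset = float(model.init_.constant_.ravel()[0]) if hasattr(model.init_, "constant_") \
                else float(np.mean(model.init_.predict(np.zeros((1, model.n_features_in_)))))
            return _Ensemble(trees, [1.0] * len(trees), offset)
        if name in ("RandomForestRegressor", "ExtraTreesRegressor"):
            w = 1.0 / len(ests)
            return _Ensemble([_from_sklearn_tree(e.tree_, 1.0) for e in ests],
                             [w] * len(ests), 0.0)
    raise TypeError(
        f"cannot extract trees from {name}; supported: LightGBM boosters, sklearn "
        "decision-tree / random-forest / gradient-boosting regressors"
    )


def _route(tree: _Tree, node: int, values: np.ndarray) -> np.ndarray:
    """Which of ``values`` go left at ``node`` (True = left)."""
    thr = tree.threshold[node]
    left = values <= thr
    nan = np.isnan(values)
    if nan.any():
        left = np.where(nan, tree.default_left[node], left)
    return left


def _predict_tree(tree: _Tree, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        node = 0
        while tree.feature[node] >= 0:
            v = X[i, tree.feature[node]]
            if np.isnan(v):
                go_left = bool(tree.default_left[node])
            else:
                go_left = v <= tree.threshold[node]
            node = tree.left[node] if go_left else tree.right[node]
        out[i] = tree.value[node]
    return out


class TreeExplainer:
    """Interventional Shapley attribution for tree ensembles.

    Walks each tree once per explained row, partitioning the background rows
    by their routing; every reachable leaf yields a closed-form contribution
    to phi for the features its path constrains.  Output is on the ensemble's
    native additive scale (raw margin for boosted classifiers, the
    prediction itself for regressors); ``output='probability'`` rescales a
    binary classifier's margin-scale phi proportionally so the additive
    identity holds on the probability scale (logged, since the sigmoid is
    nonlinear and per-feature probability attributions are then a linear
    apportionment of the margin attribution).
    """

    def __init__(self, model, background, output: str = "raw"):
        if output not in ("raw", "probability"):
            raise ValueError("output must be 'raw' or 'probability'")
        self.model = model
        self.output = output
        self.is_classifier = hasattr(model, "predict_proba")
        if output == "probability" and not self.is_classifier:
            raise ValueError("probability output requires a classifier")
        self.ensemble = _extract_ensemble(model)
        self.background = np.atleast_2d(np.asarray(background, dtype=float))
        if self.background.shape[0] == 0:
            raise ValueError("background must be non-empty")
        self.M = self.background.shape[1]
        self._w = _subset_weights(self.M)
        # binomial table C[u, i]
        self._comb = np.array(
            [[math.comb(u, i) if i <= u else 0 for i in range(self.M + 1)]
             for u in range(self.M + 1)], dtype=float
        )

    # -- native-scale prediction from the extracted trees ------------------
    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(X.shape[0], self.ensemble.offset, dtype=float)
        for tree, w in zip(self.ensemble.trees, self.ensemble.weights):
            out += w * _predict_tree(tree, X)
        return out

    def _leaf_walk(self, tree: _Tree, x: np.ndarray, phi: np.ndarray, base: list):
        """Accumulate one tree's contributions for explained row x.

        Stack state is (node, R, F, rows): R = path features that must be in
        the coalition (x satisfies the splits, the rows' z does not), F =
        features that must be out, rows = background rows consistent so far.
        """
        n_bg = self.background.shape[0]
        M, w, comb = self.M, self._w, self._comb

        stack = [(0, frozenset(), frozenset(), np.arange(n_bg))]
        while stack:
            node, R, F, rows = stack.pop()
            f = tree.feature[node]
            if f < 0:  # leaf: closed-form contribution over irrelevant features
                v = tree.value[node] * len(rows) / n_bg
                r, b = len(R), len(F)
                U = M - r - b
                if r == 0:
                    base[0] += v
                if v == 0.0:
                    continue
                if r > 0:
                    i_arr = np.arange(U + 1)
                    s_in = w[r - 1 + i_arr] @ comb[U, : U + 1]
                    for j in R:
                        phi[j] += v * s_in
                if b > 0:
                    i_arr = np.arange(U + 1)
                    s_out = w[r + i_arr] @ comb[U, : U + 1]
                    for j in F:
                        phi[j] -= v * s_out
                continue

            x_left = bool(_route(tree, node, np.array([x[f]]))[0])
            x_child = tree.left[node] if x_left else tree.right[node]
            o_child = tree.right[node] if x_left else tree.left[node]
            if f in R:
                # coalition contains f: routing follows x regardless of z
                stack.append((x_child, R, F, rows))
                continue
            z_left = _route(tree, node, self.background[rows, f])
            z_on_x_side = z_left if x_left else ~z_left
            if f in F:
                # coalition excludes f: routing follows each background row
                same, opp = rows[z_on_x_side], rows[~z_on_x_side]
                if len(same):
                    stack.append((x_child, R, F, same))
                if len(opp):
                    stack.append((o_child, R, F, opp))
            else:
                # first time f appears on this path
                same, opp = rows[z_on_x_side], rows[~z_on_x_side]
                if len(same):  # x and z agree: f stays irrelevant down x's side
                    stack.append((x_child, R, F, same))
                if len(opp):  # they disagree: each side constrains f
                    stack.append((x_child, R | {f}, F, opp))
                    stack.append((o_child, R, F | {f}, opp))

    def shap_values(self, X) -> tuple[np.ndarray, float]:
        """phi matrix (n, M) and the scalar base value."""
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        n = Xa.shape[0]
        phi = np.zeros((n, self.M))
        base_acc = 0.0
        for i in range(n):
            row_phi = np.zeros(self.M)
            row_base = 0.0
            for tree, wt in zip(self.ensemble.trees, self.ensemble.weights):
                tree_phi = np.zeros(self.M)
                tree_base = [0.0]
                self._leaf_walk(tree, Xa[i], tree_phi, tree_base)
                row_phi += wt * tree_phi
                row_base += wt * tree_base[0]
            phi[i] = row_phi
            if i == 0:
                # the base (empty coalition) is routed purely by the
                # background, hence identical for every explained row
                base_acc = row_base
        base = self.ensemble.offset + base_acc

        if self.output == "probability":
            raw_pred = self._raw_predict(Xa)
            prob_pred = self.model.predict_proba(Xa)[:, 1]
            # background probability baseline
            prob_base = float(self.model.predict_proba(self.background)[:, 1].mean())
            for i in range(n):
                gap_raw = raw_pred[i] - base
                scale = (prob_pred[i] - prob_base) / gap_raw if gap_raw != 0 else 0.0
                phi[i] *= scale
            base = prob_base
        return phi, float(base)


def tree_shap_matrix(model, table, background=None, output: str = "raw") -> ShapMatrix:
    """Explain every row of a feature table with the tree-path algorithm.

    ``table`` may be a FeatureTable or a DataFrame; ``background`` defaults
    to the table itself (sub-sampled to at most 256 rows with a fixed seed).
    """
    X = table.X if hasattr(table, "X") else table
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)))
    if background is None:
        background = X
    bg = background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) \
        else np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] > 256:
        rng = np.random.default_rng(0)
        bg = bg[rng.choice(bg.shape[0], 256, replace=False)]
    expl = TreeExplainer(model, bg, output=output)
    phi, base = expl.shap_values(X)
    if output == "probability":
        preds = pd.Series(model.predict_proba(X.to_numpy(dtype=float))[:, 1], index=X.index)
    else:
        preds = pd.Series(expl._raw_predict(X.to_numpy(dtype=float)), index=X.index)
    return ShapMatrix(
        phi=pd.DataFrame(phi, index=X.index, columns=X.columns),
        base_value=base,
        predictions=preds,
        background=pd.DataFrame(bg, columns=X.columns),
    )


def global_importance(matrix: ShapMatrix) -> GlobalImportance:
    """Mean |phi| per feature, sorted descending with name tie-break."""
    imp = matrix.phi.abs().mean(axis=0)
    df = pd.DataFrame({"importance": imp})
    df = df.sort_index().sort_values("importance", ascending=False, kind="stable")
    return GlobalImportance(df)


def summary_data(matrix: ShapMatrix, table) -> dict[str, pd.DataFrame]:
    """Beeswarm-summary data: per feature, (phi, value, value percentile).

    Features are ordered by global importance; percentiles are computed over
    the non-missing values of each column, and rows with a missing value are
    flagged rather than dropped.
    """
    X = table.X if hasattr(table, "X") else table
    if not X.index.equals(matrix.phi.index):
        raise ValueError("matrix and table must be row-aligned")
    order = global_importance(matrix).table.index
    out = {}
    for feat in order:
        vals = X[feat]
        obs = vals.dropna()
        pct = obs.rank(pct=True) if len(obs) else obs
        out[feat] = pd.DataFrame(
            {
                "phi": matrix.phi[feat],
                "value": vals,
                "value_percentile": pct.reindex(vals.index),
                "missing": vals.isna(),
            }
        )
    return out


def dependence_data(
    matrix: ShapMatrix, table, feature: str
) -> tuple[pd.DataFrame, float | None]:
    """Scatter pairs (feature value, phi) plus an optional sign-change cutoff.

    The cutoff is the zero crossing of an isotonic (monotone least-squares)
    fit of phi against the feature value, reported only when the fitted
    curve actually changes sign.
    """
    X = table.X if hasattr(table, "X") else table
    if feature not in X.columns:
        raise KeyError(f"unknown feature {feature!r}")
    df = pd.DataFrame({"value": X[feature], "phi": matrix.phi[feature]}).dropna(subset=["value"])
    cutoff = None
    if len(df) >= 3 and df["value"].nunique() > 1:
        from sklearn.isotonic import IsotonicRegression

        d = df.sort_values("value")
        rho = d["value"].corr(d["phi"], method="spearman")
        iso = IsotonicRegression(increasing=bool(rho >= 0), out_of_bounds="clip")
        fit = iso.fit_transform(d["value"].to_numpy(), d["phi"].to_numpy())
        signs = np.sign(fit)
        if (signs > 0).any() and (signs < 0).any():
            k = int(np.argmax(signs != signs[0]))
            cutoff = float((d["value"].iloc[k - 1] + d["value"].iloc[k]) / 2.0)
    return df.reset_index(drop=True), cutoff


def local_profile(explanation: ShapExplanation, top_n: int = 10) -> pd.DataFrame:
    """Per-molecule profile: top-|phi| features plus an 'other' remainder.

    The cumulative sum of the listed contributions reproduces
    prediction - base exactly.
    """
    phi = explanation.phi.sort_values(key=lambda s: s.abs(), ascending=False, kind="stable")
    top = phi.iloc[:top_n]
    rest = float(phi.iloc[top_n:].sum())
    rows = [{"feature": n, "phi": float(v)} for n, v in top.items()]
    if len(phi) > top_n:
        rows.append({"feature": "other", "phi": rest})
    df = pd.DataFrame(rows)
    df["cumulative"] = df["phi"].cumsum()
    return df


def profile_to_json(profile: pd.DataFrame, explanation: ShapExplanation, path) -> None:
    payload = {
        "base_value": explanation.base_value,
        "prediction": explanation.prediction,
        "contributions": profile.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
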