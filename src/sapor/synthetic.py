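"""Synthetic data with known ground truth for every pipeline stage.

Real descriptor tables have three properties the pipeline must cope with:
blocks of strongly rank-correlated (redundant) features, a minority of
class-separating features, and value-dependent (missing-not-at-random)
missingness.  The generators here plant all three with known answers, so
feature-selection recovery, cleaning arithmetic and explanation oracles can
be scored without any external download.

Correlated blocks are realized with a one-factor model per block: feature
j of block b is ``sqrt(w) * g_b + sqrt(1-w) * eps`` with block factors
sharing a global factor to set the between-block level.  For jointly
Gaussian pairs the population Spearman correlation is
``(6/pi) * asin(rho/2)`` of the Pearson ``rho``; ground truth reports both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import FeatureTable

__all__ = [
    "BlockSpec",
    "generate_block_table",
    "inject_mnar",
    "toy_tree_model",
    "toy_compound_set",
    "spearman_of_pearson",
]


def spearman_of_pearson(rho: float) -> float:
    """Population Spearman correlation of a bivariate Gaussian pair."""
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


@dataclass
class BlockSpec:
    """Planted-structure parameters for the correlated-block table."""

    n_blocks: int = 20
    block_size: int = 8
    within_block_corr: float = 0.9
    between_block_corr: float = 0.05
    informative_blocks: tuple[int, ...] = (0, 1, 2, 3, 4)
    class_shift: float = 1.0
    shift_attenuation: float = 0.5
    n_rows: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.between_block_corr < self.within_block_corr <= 1):
            raise ValueError("require 0 <= between < within <= 1")
        if any(b < 0 or b >= self.n_blocks for b in self.informative_blocks):
            raise ValueError("informative_blocks must index existing blocks")
        if not (0 < self.shift_attenuation < 1):
            raise ValueError("shift_attenuation must be in (0, 1)")


def generate_block_table(spec: BlockSpec) -> tuple[FeatureTable, dict]:
    """Block-correlated Gaussian features with class shifts of known location.

    In each informative block, member 0 receives the full ``class_shift`` on
    class-1 rows and every other member the attenuated shift, so the
    within-block KS-argmax is member 0 by construction.  Ground truth
    returns block membership, the expected representative per informative
    block and the planted Pearson/Spearman correlation levels.
    """
    rng = np.random.default_rng(spec.seed)
    n, B, m = spec.n_rows, spec.n_blocks, spec.block_size
    w = spec.within_block_corr
    t = spec.between_block_corr / w if w > 0 else 0.0  # factor-sharing level

    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)

    h = rng.normal(size=n)  # global factor
    width = len(str(B - 1))
    cols, data = [], []
    block_of: dict[str, int] = {}
    for b in range(B):
        g = np.sqrt(t) * h + np.sqrt(1.0 - t) * rng.normal(size=n)
        for j in range(m):
            x = np.sqrt(w) * g + np.sqrt(1.0 - w) * rng.normal(size=n)
            if b in spec.informative_blocks:
                shift = spec.class_shift if j == 0 else spec.class_shift * spec.shift_attenuation
                x = x + shift * y
            name = f"b{b:0{width}d}_f{j}"
            cols.append(name)
            data.append(x)
            block_of[name] = b
    X = pd.DataFrame(np.column_stack(data), columns=cols)
    X.index = [f"r{i:04d}" for i in range(n)]
    table = FeatureTable(X, pd.Series(y, index=X.index, name="target"), {c: "synthetic" for c in cols})
    truth = {
        "block_of": block_of,
        "expected_representative": {
            b: f"b{b:0{width}d}_f0" for b in spec.informative_blocks
        },
        "informative_blocks": tuple(spec.informative_blocks),
        "planted_within_pearson": w,
        "planted_between_pearson": spec.between_block_corr,
        "planted_within_spearman": spearman_of_pearson(w),
        "planted_between_spearman": spearman_of_pearson(spec.between_block_corr),
    }
    return table, truth


def inject_mnar(
    table: FeatureTable, columns: list[str], fraction: float, seed: int = 0
) -> FeatureTable:
    """Value-dependent missingness: blank cells above the (1-fraction) quantile.

    Deterministic given the table (the seed only breaks ties among equal
    values); realized missing fraction is within 0.02 of the target for
    continuous columns.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    out = table.copy()
    for c in columns:
        col = out.X[c]
        q = col.quantile(1.0 - fraction, interpolation="linear")
        out.X.loc[col > q, c] = np.nan
    return out


def toy_tree_model(n_features: int = 8, seed: int = 0, flavor: str = "lightgbm"):
    """Small fitted tree ensemble + background rows for explanation oracles.

    The last feature is constant in the training data, so no tree can split
    on it and its Shapley value must be exactly 0 (dummy axiom hook).
    Returns ``(model, background, X)``.
    """
    if n_features > 12:
        raise ValueError("keep toy models enumerable: n_features <= 12")
    rng = np.random.default_rng(seed)
    n = 200
    X = rng.normal(size=(n, n_features))
    X[:, -1] = 0.0  # guaranteed-unused feature
    y = (
        2.0 * X[:, 0]
        - 1.5 * X[:, 1 % n_features]
        + (X[:, 2 % n_features] * X[:, 3 % n_features] if n_features >= 4 else 0.0)
        + rng.normal(0.0, 0.1, size=n)
    )
    if flavor == "lightgbm":
        from lightgbm import LGBMRegressor

        model = LGBMRegressor(
            n_estimators=12, num_leaves=7, min_child_samples=10,
            random_state=seed, verbose=-1,
        )
    elif flavor == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(n_estimators=8, max_depth=4, random_state=seed)
    elif flavor == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingRegressor

        model = GradientBoostingRegressor(n_estimators=12, max_depth=3, random_state=seed)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    model.fit(X, y)
    background = X[rng.choice(n, size=32, replace=False)]
    return model, background, X


def toy_compound_set(scaffold_family: str, n: int) -> list[str]:
    """Programmatic SMILES with controllable structural similarity gradients.

    ``alkanes``: linear alkanes of increasing length; ``sugars_like``:
    linear polyols (ethylene glycol, glycerol, ...); ``aromatics``:
    n-alkylbenzenes.  Within a family, neighbouring members are highly
    similar under circular fingerprints; across families similarity is low.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scaffold_family == "alkanes":
        return ["C" * (k + 1) for k in range(n)]
    if scaffold_family == "sugars_like":
        return ["OC" + "C(O)" * k + "CO" for k in range(n)]
    if scaffold_family == "aromatics":
        return [("C" * k) + "c1ccccc1" for k in range(n)]
    raise ValueError(f"unknown scaffold family {scaffold_family!r}")
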