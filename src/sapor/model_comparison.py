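"""Pairwise model comparison with the variance-corrected resampled t-test.

Fold scores from repeated cross-validation are not independent: training
sets overlap, so the naive paired t-test is anti-conservative.  The
Nadeau–Bengio correction inflates the variance of the score differences by
``1/n + test_fraction / (1 - test_fraction)`` (instead of ``1/n``), with
``test_fraction = 1/k`` for k-fold CV.  All-pairs comparison applies a
Bonferroni factor equal to the number of unordered pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import CVResult

__all__ = ["ComparisonResult", "corrected_ttest", "pairwise_compare"]


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    t_stat: float
    p_raw: float
    p_adjusted: float
    n_scores: int
    correction_factor: float
    significant: bool


def corrected_ttest(scores_a, scores_b, test_fraction: float) -> tuple[float, float]:
    """Corrected resampled t-test on paired per-fold scores.

    t = mean(d) / sqrt((1/n + rho) * var(d)) with rho = test_fraction /
    (1 - test_fraction) and var the unbiased sample variance of the paired
    differences; two-sided p from Student's t with n-1 degrees of freedom.
    A degenerate all-zero difference vector gives t=0, p=1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched score vectors: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired scores")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    d = a - b
    md = d.mean()
    vd = d.var(ddof=1)
    denom2 = (1.0 / n + test_fraction / (1.0 - test_fraction)) * vd
    if denom2 == 0.0:
        if md == 0.0:
            return 0.0, 1.0
        return float(np.sign(md) * np.inf), 0.0
    t = md / np.sqrt(denom2)
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def pairwise_compare(
    results: dict[str, CVResult],
    alpha: float = 0.05,
    test_fraction: float | None = None,
) -> list[ComparisonResult]:
    """Compare all unordered model pairs on their per-fold AUROC vectors.

    All results must share the identical fold structure (same k, repeats and
    seed, hence identical folds).  Bonferroni factor = number of pairs;
    significance is declared at adjusted p < alpha.
    """
    names = sorted(results)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    ref = results[names[0]]
    for nm in names[1:]:
        r = results[nm]
        if (r.k, r.repeats, r.seed) != (ref.k, ref.repeats, ref.seed):
            raise ValueError(
                f"fold structure mismatch between {names[0]!r} and {nm!r}: "
                f"{(ref.k, ref.repeats, ref.seed)} vs {(r.k, r.repeats, r.seed)}"
            )
    tf = test_fraction if test_fraction is not None else 1.0 / ref.k
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        t, p = corrected_ttest(results[a].auroc_scores, results[b].auroc_scores, tf)
        p_adj = min(1.0, p * m)
        out.append(
            ComparisonResult(
                model_a=a, model_b=b, t_stat=t, p_raw=p, p_adjusted=p_adj,
                n_scores=len(results[a].auroc_scores),
                correction_factor=float(m), significant=p_adj < alpha,
            )
        )
    return out


def comparison_table(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
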