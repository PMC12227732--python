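"""Small statistics layer: permutation Wilcoxon, Spearman, BH, median/IQR.

The group comparison is a two-sided Wilcoxon rank-sum test evaluated by
label permutation (default N = 10,000 iterations): the observed rank sum
of the first group is compared against its permutation null, two-sidedly
around the expected rank sum, with the standard +1 correction so the
p-value is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "permutation_wilcoxon",
    "spearman",
    "bh_adjust",
    "median_iqr",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def permutation_wilcoxon(
    x, y, n_perm: int = 10_000, seed: int = 0
) -> TestResult:
    """Two-sided rank-sum test via label permutation.

    statistic = rank sum of ``x`` in the pooled mid-ranked data;
    p = (1 + #{permutations at least as extreme}) / (n_perm + 1), where
    extremeness is |rank sum - expected rank sum|.  Deterministic for a
    fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, total = x.size, pooled.size
    observed = float(ranks[:nx].sum())
    expected = nx * (total + 1) / 2.0
    obs_dev = abs(observed - expected)

    rng = np.random.default_rng(seed)
    # ranks are fixed; permuting labels == summing a random nx-subset of ranks
    perm_idx = rng.random((n_perm, total)).argsort(axis=1)[:, :nx]
    perm_sums = ranks[perm_idx].sum(axis=1)
    extreme = np.abs(perm_sums - expected) >= obs_dev - 1e-9
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return TestResult(statistic=observed, p_value=p, n_permutations=n_perm, seed=seed)


def spearman(x, y) -> float | None:
    """Spearman rank correlation with average ranks; None when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return None
    rho = sps.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type 7) quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)
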