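"""Statistical primitives used across the builders and analyses.

* One-tailed (enrichment) Fisher's exact test on 2x2 contingency tables,
  used to decide which ChIP experiments' target-gene sets are enriched for
  changed mRNAs.
* Benjamini–Hochberg step-up FDR adjustment across experiments.
* Dice coefficient for comparing responding-molecule sets between
  conditions.
* Standardized major axis (SMA) regression slope and a permutation test for
  a slope difference between two groups, used to compare degree-distribution
  regression lines between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_exact_one_tailed",
    "benjamini_hochberg",
    "dice_coefficient",
    "sma_slope",
    "sma_slope_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for target-set enrichment.

    ``a``: changed genes that are targets; ``b``: changed non-targets;
    ``c``: unchanged targets; ``d``: unchanged non-targets.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"contingency count {name} must be a non-negative integer")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("contingency table must have positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-experiment enrichment outcome (one test per ChIP experiment and
    response-direction set)."""

    experiment_id: str
    tf_name: str
    table: ContingencyTable
    p_value: float
    q_value: float = float("nan")
    direction_label: str = ""


def fisher_exact_one_tailed(t: ContingencyTable) -> float:
    """Enrichment-tail Fisher's exact test: P(X >= a) for X hypergeometric
    with population a+b+c+d, a+c successes (targets) and a+b draws (changed
    genes)."""
    return float(sps.hypergeom.sf(t.a - 1, t.total, t.a + t.c, t.a + t.b))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), clipped to 1
    and returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def dice_coefficient(set_a: Set, set_b: Set) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); undefined (error) when both empty."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a and not set_b:
        raise ValueError("dice coefficient undefined for two empty sets")
    return 2.0 * len(set_a & set_b) / (len(set_a) + len(set_b))


def _as_xy(x: Sequence[float], y: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("SMA regression requires at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("SMA regression undefined for zero-variance input")
    return x, y


def sma_slope(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Standardized major axis slope and intercept.

    slope = sign(corr(x, y)) * sd(y)/sd(x); the intercept passes the line
    through the centroid.  A zero correlation takes the positive branch.
    """
    x, y = _as_xy(x, y)
    r = np.corrcoef(x, y)[0, 1]
    slope = (1.0 if r >= 0 else -1.0) * np.std(y, ddof=1) / np.std(x, ddof=1)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def sma_slope_test(
    x1: Sequence[float],
    y1: Sequence[float],
    x2: Sequence[float],
    y2: Sequence[float],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> float:
    """Permutation p-value for H0: the two groups share an SMA slope.

    The statistic is |slope1 − slope2|; the null distribution is built by
    permuting group labels over the pooled (x, y) pairs.  Returns
    (1 + #{null >= observed}) / (B + 1), in (0, 1].
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x1, y1 = _as_xy(x1, y1)
    x2, y2 = _as_xy(x2, y2)
    observed = abs(sma_slope(x1, y1)[0] - sma_slope(x2, y2)[0])
    pooled_x = np.concatenate([x1, x2])
    pooled_y = np.concatenate([y1, y2])
    n1 = x1.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        idx = rng.permutation(pooled_x.size)
        g1, g2 = idx[:n1], idx[n1:]
        try:
            s1, _ = sma_slope(pooled_x[g1], pooled_y[g1])
            s2, _ = sma_slope(pooled_x[g2], pooled_y[g2])
        except ValueError:
            # degenerate permutation (zero variance); count as extreme,
            # keeping the test conservative
            exceed += 1
            continue
        if abs(s1 - s2) >= observed:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)
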