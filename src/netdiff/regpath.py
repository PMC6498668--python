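"""Penalty-path machinery: lambda maxima and geometric grids.

``lambda1_max`` is the smallest sparsity penalty at which the joint
solution is identically zero (the lasso lambda-max of both conditions
combined).  ``lambda2_max`` is an upper bound on the smallest fusion
penalty at which both condition-specific coefficient vectors collapse to
a common vector beta*; the bound is derived from the subgradient
stationarity conditions at beta* and is what the grids anchor on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import DesignPair, lasso_cd

__all__ = [
    "LambdaGrid",
    "STABILITY_GRID_DEFAULTS",
    "CV_GRID_DEFAULTS",
    "lambda1_max",
    "common_beta_star",
    "lambda2_max",
    "build_grid",
    "network_lambda_grid",
]

# (alpha1, alpha2, k1, k2) decay factors / sizes for the two standard uses.
STABILITY_GRID_DEFAULTS = (0.7, 0.8, 10, 10)
CV_GRID_DEFAULTS = (0.6952, 0.3728, 20, 8)


@dataclass
class LambdaGrid:
    """Geometric (lam1, lam2) grid, largest-first for warm-started paths."""

    lam1_values: np.ndarray
    lam2_values_by_lam1: dict[float, np.ndarray]
    alpha1: float
    alpha2: float
    k1: int
    k2: int

    @property
    def n_pairs(self) -> int:
        return self.k1 * self.k2

    def pairs(self):
        """Iterate (lam1, lam2) pairs in warm-start order (both decreasing)."""
        for lam1 in self.lam1_values:
            for lam2 in self.lam2_values_by_lam1[float(lam1)]:
                yield float(lam1), float(lam2)


def lambda1_max(design: DesignPair) -> float:
    """Smallest lam1 zeroing the joint solution (at lam2 = 0)."""
    if design.design_a.size == 0 or design.design_b.size == 0:
        raise ValueError("empty design")
    ca = 2.0 * np.abs(design.design_a.T @ design.response_a)
    cb = 2.0 * np.abs(design.design_b.T @ design.response_b)
    return float(max(ca.max(), cb.max()))


def common_beta_star(
    design: DesignPair, lam1: float, init: np.ndarray | None = None
) -> np.ndarray:
    """Common coefficient vector minimizing the stacked two-condition lasso.

    Minimizes ||x - X b||^2 + ||x~ - X~ b||^2 + 2*lam1*||b||_1, i.e. the
    joint objective restricted to beta = beta~ (where the fusion penalty
    vanishes and the two l1 terms merge).
    """
    if lam1 < 0:
        raise ValueError("lam1 must be nonnegative")
    z = np.vstack([design.design_a, design.design_b])
    y = np.concatenate([design.response_a, design.response_b])
    return lasso_cd(y, z, lam1, penalty_scale=2.0, init=init)


def lambda2_max(
    design: DesignPair, lam1: float, beta_star: np.ndarray | None = None
) -> float:
    """Upper bound on the fusion penalty forcing beta = beta~ = beta*."""
    if lam1 < 0:
        raise ValueError("lam1 must be nonnegative")
    if beta_star is None:
        beta_star = common_beta_star(design, lam1)
    ra = design.response_a - design.design_a @ beta_star
    rb = design.response_b - design.design_b @ beta_star
    ta = lam1 + np.abs(2.0 * (design.design_a.T @ ra))
    tb = lam1 + np.abs(2.0 * (design.design_b.T @ rb))
    return float(max(ta.max(), tb.max()))


def build_grid(
    design: DesignPair,
    alpha1: float = STABILITY_GRID_DEFAULTS[0],
    alpha2: float = STABILITY_GRID_DEFAULTS[1],
    k1: int = STABILITY_GRID_DEFAULTS[2],
    k2: int = STABILITY_GRID_DEFAULTS[3],
) -> LambdaGrid:
    """Geometric penalty grid anchored at lambda1_max / lambda2_max.

    S1 = {lam1max * alpha1^m} for m = 0..k1-1; for each lam1 in S1,
    S2(lam1) = {lam2max(lam1) * alpha2^m} for m = 0..k2-1.
    """
    if not (0 < alpha1 < 1 and 0 < alpha2 < 1):
        raise ValueError("decay factors must lie in (0, 1)")
    if k1 < 1 or k2 < 1:
        raise ValueError("grid sizes must be >= 1")
    l1max = lambda1_max(design)
    lam1_values = _geometric(l1max, alpha1, k1)
    lam2_by: dict[float, np.ndarray] = {}
    beta_star = None  # warm-start the common-solution path, largest lam1 first
    for lam1 in lam1_values:
        beta_star = common_beta_star(design, float(lam1), init=beta_star)
        l2max = lambda2_max(design, float(lam1), beta_star=beta_star)
        lam2_by[float(lam1)] = _geometric(l2max, alpha2, k2)
    return LambdaGrid(lam1_values, lam2_by, alpha1, alpha2, k1, k2)


def network_lambda_grid(
    pair,
    alpha1: float = STABILITY_GRID_DEFAULTS[0],
    alpha2: float = STABILITY_GRID_DEFAULTS[1],
    k1: int = STABILITY_GRID_DEFAULTS[2],
    k2: int = STABILITY_GRID_DEFAULTS[3],
) -> LambdaGrid:
    """Shared penalty grid for a whole-network fit.

    Anchored at the largest per-gene lambda1_max, and for each lam1 at the
    largest per-gene lambda2_max, so every gene's solution is zero (resp.
    fused) at the top of the grid.
    """
    from .network import design_for_gene  # local import to avoid a cycle
    from .solver import center_columns

    if not (0 < alpha1 < 1 and 0 < alpha2 < 1):
        raise ValueError("decay factors must lie in (0, 1)")
    if k1 < 1 or k2 < 1:
        raise ValueError("grid sizes must be >= 1")
    xa, _ = center_columns(pair.expr_a)
    xb, _ = center_columns(pair.expr_b)
    designs = [
        design_for_gene(xa, xb, i, pair.gene_names) for i in range(pair.n_genes)
    ]
    l1max = max(lambda1_max(d) for d in designs)
    lam1_values = _geometric(l1max, alpha1, k1)
    lam2_by: dict[float, np.ndarray] = {}
    beta_stars: list[np.ndarray | None] = [None] * len(designs)
    for lam1 in lam1_values:
        l2max = 0.0
        for idx, d in enumerate(designs):
            beta_stars[idx] = common_beta_star(d, float(lam1), init=beta_stars[idx])
            l2max = max(l2max, lambda2_max(d, float(lam1), beta_star=beta_stars[idx]))
        lam2_by[float(lam1)] = _geometric(l2max, alpha2, k2)
    return LambdaGrid(lam1_values, lam2_by, alpha1, alpha2, k1, k2)


def _geometric(top: float, alpha: float, k: int) -> np.ndarray:
    vals = np.empty(k)
    vals[0] = top
    for m in range(1, k):
        vals[m] = vals[m - 1] * alpha
    return vals
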