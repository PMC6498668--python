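"""Whole-network drivers: per-gene joint fits, baselines, filters, ranking.

A directed network over p genes is encoded as a p x p coefficient matrix
B with b[j, i] the effect of gene j on gene i — column i of B is gene i's
regression coefficient vector, and the diagonal is structurally zero.
The differential network is the nonzero part of B - B~ after the
changed-edge magnitude criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solver import DesignPair, SolverConfig, center_columns, lasso_cd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionPair",
    "NetworkPair",
    "FilterConfig",
    "design_for_gene",
    "filter_genes",
    "infer_network_pair",
    "fit_network_path",
    "fit_network_grid",
    "fit_separate_lasso_grid",
    "separate_lasso_pair",
    "changed_edge_threshold",
    "changed_edges",
    "rank_changed_edges",
]


@dataclass
class ExpressionPair:
    """Expression matrices (samples x genes) for the same genes, two conditions."""

    expr_a: np.ndarray
    expr_b: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expr_a = np.asarray(self.expr_a, dtype=float)
        self.expr_b = np.asarray(self.expr_b, dtype=float)
        if self.expr_a.ndim != 2 or self.expr_b.ndim != 2:
            raise ValueError("expression matrices must be 2-D (samples x genes)")
        if self.expr_a.shape[1] != self.expr_b.shape[1]:
            raise ValueError("both conditions must cover the same genes")
        if not (np.all(np.isfinite(self.expr_a)) and np.all(np.isfinite(self.expr_b))):
            raise ValueError("expression matrices contain non-finite entries")
        if not self.gene_names:
            self.gene_names = [f"G{j}" for j in range(self.n_genes)]
        if len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length mismatch")

    @property
    def n_genes(self) -> int:
        return self.expr_a.shape[1]


@dataclass
class NetworkPair:
    """Coefficient matrices under both conditions and their difference."""

    b: np.ndarray
    b_tilde: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.b_tilde = np.asarray(self.b_tilde, dtype=float)
        p = self.b.shape[0]
        if self.b.shape != (p, p) or self.b_tilde.shape != (p, p):
            raise ValueError("coefficient matrices must be square and same shape")
        if np.any(np.diag(self.b) != 0) or np.any(np.diag(self.b_tilde) != 0):
            raise ValueError("diagonals must be zero (no self-loops)")
        if not self.gene_names:
            self.gene_names = [f"G{j}" for j in range(p)]
        if len(self.gene_names) != p:
            raise ValueError("gene_names length mismatch")

    @property
    def delta(self) -> np.ndarray:
        return self.b - self.b_tilde

    @property
    def n_genes(self) -> int:
        return self.b.shape[0]


@dataclass
class FilterConfig:
    """Percentile cutoffs for the informative-gene filters and the
    changed-edge magnitude threshold T."""

    expr_percentile: float = 30.0
    cov_percentile: float = 70.0
    t_percentile: float = 20.0

    def __post_init__(self) -> None:
        for name in ("expr_percentile", "cov_percentile", "t_percentile"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")


def design_for_gene(
    expr_a_centered: np.ndarray,
    expr_b_centered: np.ndarray,
    i: int,
    gene_names: list[str],
) -> DesignPair:
    """Extract gene i's regression problem from centered expression matrices."""
    keep = [j for j in range(expr_a_centered.shape[1]) if j != i]
    return DesignPair(
        response_a=expr_a_centered[:, i],
        design_a=expr_a_centered[:, keep],
        response_b=expr_b_centered[:, i],
        design_b=expr_b_centered[:, keep],
        predictor_labels=[gene_names[j] for j in keep],
    )


def filter_genes(pair: ExpressionPair, config: FilterConfig | None = None) -> ExpressionPair:
    """Two-stage informative-gene filter.

    Step 1 removes genes whose pooled mean expression is at or below the
    ``expr_percentile`` percentile; step 2 removes remaining genes whose
    pooled coefficient of variation (sd/mean) is at or below the
    ``cov_percentile`` percentile.  Gene order is preserved.
    """
    config = config or FilterConfig()
    if pair.expr_a.shape[0] < 2 or pair.expr_b.shape[0] < 2:
        raise ValueError("need at least 2 samples per condition")
    pooled = np.vstack([pair.expr_a, pair.expr_b])
    means = pooled.mean(axis=0)
    cutoff = np.percentile(means, config.expr_percentile)
    keep1 = np.flatnonzero(means > cutoff)
    if keep1.size == 0:
        raise ValueError("expression filter removed all genes")
    sub_means = means[keep1]
    sds = pooled[:, keep1].std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        covs = np.where(sub_means != 0, sds / sub_means, np.inf)
    cov_cutoff = np.percentile(covs, config.cov_percentile)
    keep = keep1[covs > cov_cutoff]
    if keep.size == 0:
        raise ValueError("CoV filter removed all genes")
    return ExpressionPair(
        pair.expr_a[:, keep],
        pair.expr_b[:, keep],
        [pair.gene_names[j] for j in keep],
    )


def _network_lipschitz(ga: np.ndarray, gb: np.ndarray, mode: str) -> float:
    if mode == "eigen":
        lip = 2.0 * (np.linalg.eigvalsh(ga)[-1] + np.linalg.eigvalsh(gb)[-1])
    else:
        lip = 2.0 * (np.trace(ga) + np.trace(gb))
    if lip <= 0:
        raise ValueError("all-zero expression admits no valid step size")
    return float(lip)


def _solve_network_matrix(
    ga: np.ndarray,
    gb: np.ndarray,
    lam1_cols: np.ndarray,
    lam2_cols: np.ndarray,
    config: SolverConfig,
    lip: float,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Proximal-gradient solve of all genes' joint regressions at once.

    Works on the full p x p Gram matrices with the zero-diagonal
    constraint enforced inside the (separable) prox, which makes each
    column identical to the single-gene solve with its own column
    removed.  ``lam1_cols``/``lam2_cols`` give per-gene penalties, so
    gene-specific grids cost nothing extra.
    """
    from .solver import prox_pair

    p = ga.shape[0]
    step = 1.0 / lip
    if init is None:
        b = np.zeros((p, p))
        bt = np.zeros((p, p))
    else:
        b, bt = init[0].copy(), init[1].copy()
    l1e = np.asarray(lam1_cols, dtype=float)[None, :] * step
    l2e = np.asarray(lam2_cols, dtype=float)[None, :] * step
    converged = False
    for _ in range(config.max_iter):
        ta = b - step * 2.0 * (ga @ b - ga)
        tb = bt - step * 2.0 * (gb @ bt - gb)
        new_b, new_bt = prox_pair(ta, tb, l1e, l2e)
        np.fill_diagonal(new_b, 0.0)
        np.fill_diagonal(new_bt, 0.0)
        num = np.sqrt(
            np.linalg.norm(new_b - b) ** 2 + np.linalg.norm(new_bt - bt) ** 2
        )
        den = max(1.0, np.sqrt(np.linalg.norm(b) ** 2 + np.linalg.norm(bt) ** 2))
        b, bt = new_b, new_bt
        if num / den <= config.tol:
            converged = True
            break
    return b, bt, converged


def fit_network_path(
    pair: ExpressionPair,
    lam_pairs: list[tuple[float, float]],
    config: SolverConfig | None = None,
) -> list[NetworkPair]:
    """Fit the full network at each (lam1, lam2) pair, warm-started.

    ``lam_pairs`` should be ordered largest-first so warm starts move from
    sparse to dense solutions.  Returns one NetworkPair per penalty pair.
    """
    config = config or SolverConfig()
    p = pair.n_genes
    if p < 2:
        raise ValueError("need at least 2 genes")
    xa, _ = center_columns(pair.expr_a)
    xb, _ = center_columns(pair.expr_b)
    ga = xa.T @ xa
    gb = xb.T @ xb
    lip = _network_lipschitz(ga, gb, config.step_mode)
    ones = np.ones(p)
    out = []
    state = None
    for lam1, lam2 in lam_pairs:
        b, bt, ok = _solve_network_matrix(
            ga, gb, lam1 * ones, lam2 * ones, config, lip, init=state
        )
        state = (b, bt)
        if not ok:
            logger.warning(
                "network fit did not converge at lam1=%.4g lam2=%.4g", lam1, lam2
            )
        conv = np.full(p, ok)
        out.append(NetworkPair(b.copy(), bt.copy(), list(pair.gene_names), conv))
    return out


def infer_network_pair(
    pair: ExpressionPair,
    lam1: float,
    lam2: float,
    config: SolverConfig | None = None,
) -> NetworkPair:
    """Joint two-condition network fit at a single penalty pair."""
    return fit_network_path(pair, [(lam1, lam2)], config)[0]


def _pergene_lambda1_max(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Per-gene lasso lambda-max from the two Gram matrices."""
    p = ga.shape[0]
    off = ~np.eye(p, dtype=bool)
    ca = np.where(off, 2.0 * np.abs(ga), 0.0).max(axis=0)
    cb = np.where(off, 2.0 * np.abs(gb), 0.0).max(axis=0)
    return np.maximum(ca, cb)


def fit_network_grid(
    pair: ExpressionPair,
    alpha1: float,
    alpha2: float,
    k1: int,
    k2: int,
    config: SolverConfig | None = None,
) -> list[NetworkPair]:
    """Fit the network on a per-gene penalty grid of shared exponents.

    Grid point (m1, m2) solves gene i at lam1 = lam1max_i * alpha1^m1 and
    lam2 = lam2max_i(lam1) * alpha2^m2, so every gene's path spans the
    same relative range of its own penalty scale regardless of its
    connectivity.  Returns the k1*k2 networks in (m1-major, m2-minor)
    order, warm-started along the path.
    """
    from .solver import _cd_kernel

    config = config or SolverConfig()
    p = pair.n_genes
    if p < 2:
        raise ValueError("need at least 2 genes")
    if not (0 < alpha1 < 1 and 0 < alpha2 < 1) or k1 < 1 or k2 < 1:
        raise ValueError("invalid grid parameters")
    xa, _ = center_columns(pair.expr_a)
    xb, _ = center_columns(pair.expr_b)
    ga = xa.T @ xa
    gb = xb.T @ xb
    lip = _network_lipschitz(ga, gb, config.step_mode)
    l1max = _pergene_lambda1_max(ga, gb)
    gsum = ga + gb
    idx = np.arange(p)
    sub_grams = [np.ascontiguousarray(gsum[np.ix_(idx != i, idx != i)]) for i in range(p)]
    sub_c = [gsum[idx != i, i].copy() for i in range(p)]
    beta_stars = [np.zeros(p - 1) for _ in range(p)]

    out: list[NetworkPair] = []
    state = None
    for m1 in range(k1):
        lam1_cols = l1max * alpha1**m1
        # per-gene fused upper bound lam2max via the common stacked lasso
        lam2max_cols = np.empty(p)
        for i in range(p):
            beta_stars[i], _ = _cd_kernel(
                sub_grams[i], sub_c[i], 2.0 * lam1_cols[i], beta_stars[i], 1e-8, 100_000
            )
            resid_a = ga[idx != i, i] - ga[np.ix_(idx != i, idx != i)] @ beta_stars[i]
            resid_b = gb[idx != i, i] - gb[np.ix_(idx != i, idx != i)] @ beta_stars[i]
            lam2max_cols[i] = lam1_cols[i] + 2.0 * max(
                np.abs(resid_a).max(), np.abs(resid_b).max()
            )
        for m2 in range(k2):
            lam2_cols = lam2max_cols * alpha2**m2
            b, bt, ok = _solve_network_matrix(
                ga, gb, lam1_cols, lam2_cols, config, lip, init=state
            )
            state = (b, bt)
            if not ok:
                logger.warning("grid point (%d, %d) did not converge", m1, m2)
            out.append(
                NetworkPair(b.copy(), bt.copy(), list(pair.gene_names), np.full(p, ok))
            )
    return out


def fit_separate_lasso_grid(
    pair: ExpressionPair, alpha1: float, k1: int
) -> list[NetworkPair]:
    """Per-condition lasso baseline on a per-gene lam1 grid (shared exponents)."""
    from .solver import _cd_kernel

    p = pair.n_genes
    if p < 2:
        raise ValueError("need at least 2 genes")
    if not 0 < alpha1 < 1 or k1 < 1:
        raise ValueError("invalid grid parameters")
    xa, _ = center_columns(pair.expr_a)
    xb, _ = center_columns(pair.expr_b)
    ga = xa.T @ xa
    gb = xb.T @ xb
    idx = np.arange(p)
    bs = [np.zeros((p, p)) for _ in range(k1)]
    bts = [np.zeros((p, p)) for _ in range(k1)]
    for i in range(p):
        rows = idx != i
        gram_a = np.ascontiguousarray(ga[np.ix_(rows, rows)])
        gram_b = np.ascontiguousarray(gb[np.ix_(rows, rows)])
        ca, cb = ga[rows, i].copy(), gb[rows, i].copy()
        l1max_a = 2.0 * np.abs(ca).max()
        l1max_b = 2.0 * np.abs(cb).max()
        ba = np.zeros(p - 1)
        bb = np.zeros(p - 1)
        for m1 in range(k1):
            ba, _ = _cd_kernel(gram_a, ca, l1max_a * alpha1**m1, ba, 1e-8, 100_000)
            bb, _ = _cd_kernel(gram_b, cb, l1max_b * alpha1**m1, bb, 1e-8, 100_000)
            bs[m1][rows, i] = ba
            bts[m1][rows, i] = bb
    return [NetworkPair(bs[m], bts[m], list(pair.gene_names)) for m in range(k1)]


def separate_lasso_pair(pair: ExpressionPair, lam1: float) -> NetworkPair:
    """Baseline: infer each condition's network by p independent lasso fits."""
    p = pair.n_genes
    if p < 2:
        raise ValueError("need at least 2 genes")
    xa, _ = center_columns(pair.expr_a)
    xb, _ = center_columns(pair.expr_b)
    b = np.zeros((p, p))
    bt = np.zeros((p, p))
    idx = np.arange(p)
    for i in range(p):
        rows = idx[idx != i]
        b[rows, i] = lasso_cd(xa[:, i], xa[:, rows], lam1)
        bt[rows, i] = lasso_cd(xb[:, i], xb[:, rows], lam1)
    return NetworkPair(b, bt, list(pair.gene_names))


def changed_edge_threshold(net: NetworkPair, t_percentile: float = 20.0) -> float:
    """Magnitude floor T: the ``t_percentile`` percentile of all nonzero
    coefficient magnitudes pooled across both networks (0 if none)."""
    mags = np.concatenate([np.abs(net.b).ravel(), np.abs(net.b_tilde).ravel()])
    mags = mags[mags > 0]
    if mags.size == 0:
        return 0.0
    return float(np.percentile(mags, t_percentile))


def changed_edges(net: NetworkPair, t_threshold: float) -> np.ndarray:
    """Boolean mask of edges regarded as changed between conditions.

    An entry (j, i) is changed iff the absolute difference is at least a
    one-fold change relative to the smaller magnitude AND the larger
    magnitude clears the floor T (guarding against near-zero pairs).
    """
    if t_threshold < 0:
        raise ValueError("t_threshold must be nonnegative")
    ab = np.abs(net.b)
    abt = np.abs(net.b_tilde)
    diff = np.abs(net.b_tilde - net.b)
    mask = (diff >= np.minimum(ab, abt)) & (np.maximum(ab, abt) >= t_threshold)
    mask &= diff > 0
    np.fill_diagonal(mask, False)
    return mask


def rank_changed_edges(freqs, net: NetworkPair) -> pd.DataFrame:
    """Table of candidate changed edges ranked by stability frequency.

    Rows are the entries with nonzero changed-edge frequency, sorted by
    delta_r descending, ties broken by |delta_b| descending, then by
    (source, target) label order.
    """
    delta_r = np.asarray(freqs.delta_r, dtype=float)
    if delta_r.shape != net.b.shape:
        raise ValueError("frequency/coefficient shape mismatch")
    rows_j, cols_i = np.nonzero(delta_r)
    records = []
    for j, i in zip(rows_j, cols_i):
        records.append(
            {
                "source_gene": net.gene_names[j],
                "target_gene": net.gene_names[i],
                "b": net.b[j, i],
                "b_tilde": net.b_tilde[j, i],
                "delta_b": net.b[j, i] - net.b_tilde[j, i],
                "delta_r": delta_r[j, i],
            }
        )
    table = pd.DataFrame(
        records,
        columns=["source_gene", "target_gene", "b", "b_tilde", "delta_b", "delta_r"],
    )
    if len(table):
        table["_abs_db"] = table["delta_b"].abs()
        table = table.sort_values(
            by=["delta_r", "_abs_db", "source_gene", "target_gene"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).drop(columns="_abs_db")
        table = table.reset_index(drop=True)
    return table
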