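"""Model selection: K-fold cross-validation (two-SE rule) and stability selection.

Cross-validation picks a single (lam1, lam2) pair; stability selection
instead refits the network on random half-samples over a penalty grid and
scores each edge (and each edge change) by its selection frequency, which
ranks edges by reliability rather than committing to one penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import (
    ExpressionPair,
    NetworkPair,
    changed_edge_threshold,
    changed_edges,
    fit_network_path,
)
from .regpath import LambdaGrid
from .solver import CoeffPair, DesignPair, SolverConfig, solve_joint

__all__ = [
    "CVResult",
    "StabilityFrequencies",
    "cross_validate",
    "cross_validate_network",
    "two_se_select",
    "stability_select",
    "stability_select_grid",
    "stability_select_separate",
    "stability_select_separate_grid",
    "lasso_cv_two_se",
    "select_edges_by_threshold",
]


@dataclass
class CVResult:
    pe: np.ndarray  # k1 x k2 prediction errors
    se: np.ndarray  # matching standard errors across folds
    lam1_min: float
    lam2_min: float
    lam1_opt: float
    lam2_opt: float
    grid: LambdaGrid | None = None


@dataclass
class StabilityFrequencies:
    """Half-sample selection frequencies for edges and edge changes.

    ``r``/``r_tilde`` count nonzero coefficients per condition, ``delta_r``
    counts changed edges; all are proportions of the 2*N*K refits.
    """

    r: np.ndarray
    r_tilde: np.ndarray
    delta_r: np.ndarray
    n_runs: int
    n_pairs: int

    def __post_init__(self) -> None:
        for m in (self.r, self.r_tilde, self.delta_r):
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("frequencies must lie in [0, 1]")


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def _cv_fold_pe(
    design: DesignPair,
    grid: LambdaGrid,
    folds_a: list[np.ndarray],
    folds_b: list[np.ndarray],
    solver_config: SolverConfig,
) -> np.ndarray:
    """Held-out squared error per (fold, lam1, lam2) for one design pair."""
    na, nb = design.response_a.size, design.response_b.size
    folds = len(folds_a)
    k1, k2 = grid.k1, grid.k2
    fold_pe = np.zeros((folds, k1, k2))
    for f in range(folds):
        test_a, test_b = folds_a[f], folds_b[f]
        train_a = np.setdiff1d(np.arange(na), test_a)
        train_b = np.setdiff1d(np.arange(nb), test_b)
        za_tr = design.design_a[train_a]
        zb_tr = design.design_b[train_b]
        ya_tr = design.response_a[train_a]
        yb_tr = design.response_b[train_b]
        # recenter training split; apply its means to the held-out split
        mu_za = za_tr.mean(axis=0)
        mu_zb = zb_tr.mean(axis=0)
        mu_ya = ya_tr.mean()
        mu_yb = yb_tr.mean()
        sub = DesignPair(
            ya_tr - mu_ya, za_tr - mu_za, yb_tr - mu_yb, zb_tr - mu_zb,
            list(design.predictor_labels),
        )
        za_te = design.design_a[test_a] - mu_za
        zb_te = design.design_b[test_b] - mu_zb
        ya_te = design.response_a[test_a] - mu_ya
        yb_te = design.response_b[test_b] - mu_yb
        init: CoeffPair | None = None
        for i1, lam1 in enumerate(grid.lam1_values):
            for i2, lam2 in enumerate(grid.lam2_values_by_lam1[float(lam1)]):
                cfg = SolverConfig(
                    lam1=float(lam1), lam2=float(lam2),
                    tol=solver_config.tol, max_iter=solver_config.max_iter,
                    step_mode=solver_config.step_mode,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = solve_joint(sub, cfg, init=init, keep_objective_path=False)
                init = res.coeffs
                ra = ya_te - za_te @ res.coeffs.beta
                rb = yb_te - zb_te @ res.coeffs.beta_tilde
                fold_pe[f, i1, i2] = ra @ ra + rb @ rb
    return fold_pe


def _cv_result(fold_pe: np.ndarray, grid: LambdaGrid) -> CVResult:
    folds = fold_pe.shape[0]
    pe = fold_pe.mean(axis=0)
    se = fold_pe.std(axis=0, ddof=1) / np.sqrt(folds)
    lam1_min, lam2_min, lam1_opt, lam2_opt = two_se_select(pe, se, grid)
    return CVResult(pe, se, lam1_min, lam2_min, lam1_opt, lam2_opt, grid)


def cross_validate(
    design: DesignPair,
    grid: LambdaGrid,
    folds: int = 5,
    seed: int = 0,
    solver_config: SolverConfig | None = None,
) -> CVResult:
    """K-fold CV of the joint solver over a penalty grid, with the two-SE rule.

    Samples of each condition are partitioned independently into ``folds``
    folds; each training split is recentered and its column means applied
    to the held-out split.  PE is the held-out squared error summed over
    both conditions, averaged over folds; SE is the across-fold standard
    deviation of PE divided by sqrt(folds).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    na, nb = design.response_a.size, design.response_b.size
    if na < folds or nb < folds:
        raise ValueError("fewer samples than folds")
    solver_config = solver_config or SolverConfig()
    rng = np.random.default_rng(seed)
    folds_a = _fold_indices(na, folds, rng)
    folds_b = _fold_indices(nb, folds, rng)
    fold_pe = _cv_fold_pe(design, grid, folds_a, folds_b, solver_config)
    return _cv_result(fold_pe, grid)


def cross_validate_network(
    pair: ExpressionPair,
    grid: LambdaGrid,
    folds: int = 5,
    seed: int = 0,
    solver_config: SolverConfig | None = None,
) -> CVResult:
    """Globally pooled CV over a whole network: per-gene held-out errors
    are summed across genes before applying the two-SE rule, selecting one
    (lam1, lam2) pair shared by all genes."""
    from .network import center_columns, design_for_gene

    if folds < 2:
        raise ValueError("folds must be >= 2")
    na, nb = pair.expr_a.shape[0], pair.expr_b.shape[0]
    if na < folds or nb < folds:
        raise ValueError("fewer samples than folds")
    solver_config = solver_config or SolverConfig()
    rng = np.random.default_rng(seed)
    folds_a = _fold_indices(na, folds, rng)
    folds_b = _fold_indices(nb, folds, rng)
    xa, _ = center_columns(pair.expr_a)
    xb, _ = center_columns(pair.expr_b)
    total = np.zeros((folds, grid.k1, grid.k2))
    for i in range(pair.n_genes):
        design = design_for_gene(xa, xb, i, pair.gene_names)
        total += _cv_fold_pe(design, grid, folds_a, folds_b, solver_config)
    return _cv_result(total, grid)


def two_se_select(
    pe: np.ndarray, se: np.ndarray, grid: LambdaGrid
) -> tuple[float, float, float, float]:
    """Two-standard-error rule on a PE/SE table over a LambdaGrid.

    Finds the PE minimizer (lam1_min, lam2_min), then among grid pairs
    with PE <= PE_min + 2*SE_min, lam1 >= lam1_min and lam2 >= lam2_min,
    picks the largest lam1, breaking ties by the largest lam2.
    """
    pe = np.asarray(pe, dtype=float)
    se = np.asarray(se, dtype=float)
    if pe.shape != (grid.k1, grid.k2) or se.shape != pe.shape:
        raise ValueError("pe/se shape must match the grid")
    i_min, j_min = np.unravel_index(np.argmin(pe), pe.shape)
    lam1_min = float(grid.lam1_values[i_min])
    lam2_min = float(grid.lam2_values_by_lam1[lam1_min][j_min])
    threshold = pe[i_min, j_min] + 2.0 * se[i_min, j_min]
    best: tuple[float, float] | None = None
    for i1, lam1 in enumerate(grid.lam1_values):
        lam2s = grid.lam2_values_by_lam1[float(lam1)]
        for i2, lam2 in enumerate(lam2s):
            if pe[i1, i2] > threshold:
                continue
            if lam1 < lam1_min or lam2 < lam2_min:
                continue
            cand = (float(lam1), float(lam2))
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] > best[1]):
                best = cand
    if best is None:  # minimizer always qualifies
        best = (lam1_min, lam2_min)
    return lam1_min, lam2_min, best[0], best[1]


def _half_split(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random split into two halves; the first half takes any extra sample."""
    perm = rng.permutation(n)
    cut = (n + 1) // 2
    return np.sort(perm[:cut]), np.sort(perm[cut:])


def _stability_core(
    pair: ExpressionPair,
    fitter,
    k: int,
    n_runs: int,
    seed: int,
    apply_change_criteria: bool,
    t_percentile: float,
) -> StabilityFrequencies:
    na, nb = pair.expr_a.shape[0], pair.expr_b.shape[0]
    if na < 4 or nb < 4:
        raise ValueError("need at least 4 samples per condition")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if k < 1:
        raise ValueError("need at least one penalty point")
    rng = np.random.default_rng(seed)
    p = pair.n_genes
    r = np.zeros((p, p))
    r_tilde = np.zeros((p, p))
    delta_r = np.zeros((p, p))
    for _ in range(n_runs):
        halves_a = _half_split(na, rng)
        halves_b = _half_split(nb, rng)
        for ia, ib in zip(halves_a, halves_b):
            sub = ExpressionPair(pair.expr_a[ia], pair.expr_b[ib], list(pair.gene_names))
            for net in fitter(sub):
                r += net.b != 0
                r_tilde += net.b_tilde != 0
                if apply_change_criteria:
                    t = changed_edge_threshold(net, t_percentile)
                    delta_r += changed_edges(net, t)
                else:
                    delta_r += net.delta != 0
    norm = 2.0 * n_runs * k
    return StabilityFrequencies(r / norm, r_tilde / norm, delta_r / norm, n_runs, k)


def stability_select(
    pair: ExpressionPair,
    lam_pairs: list[tuple[float, float]],
    n_runs: int = 50,
    seed: int = 0,
    solver_config: SolverConfig | None = None,
    apply_change_criteria: bool = True,
    t_percentile: float = 20.0,
) -> StabilityFrequencies:
    """Half-sample stability selection of edges and edge changes.

    For each of ``n_runs`` repetitions, each condition's samples are
    randomly split into two halves (independently per condition) and the
    full network is refit jointly on each half at every penalty pair; an
    entry's frequency is the fraction of the 2*n_runs*K refits selecting
    it.  Changed-edge counts apply the magnitude criteria per refit when
    ``apply_change_criteria`` is set, else count any nonzero difference.
    """
    if not lam_pairs:
        raise ValueError("need at least one (lam1, lam2) pair")

    def fitter(sub: ExpressionPair):
        return fit_network_path(sub, lam_pairs, solver_config)

    return _stability_core(
        pair, fitter, len(lam_pairs), n_runs, seed, apply_change_criteria, t_percentile
    )


def stability_select_grid(
    pair: ExpressionPair,
    alpha1: float = 0.7,
    alpha2: float = 0.8,
    k1: int = 10,
    k2: int = 10,
    n_runs: int = 50,
    seed: int = 0,
    solver_config: SolverConfig | None = None,
    apply_change_criteria: bool = True,
    t_percentile: float = 20.0,
) -> StabilityFrequencies:
    """Stability selection over per-gene penalty grids.

    Like :func:`stability_select`, but each refit solves every gene on its
    own geometric grid (anchored at that gene's lambda maxima, shared
    exponents alpha1^m1 / alpha2^m2), so the K = k1*k2 grid points span
    the same relative penalty range for every gene regardless of its
    connectivity.  Defaults follow the standard stability grid
    (0.7, 0.8, 10, 10).
    """
    from .network import fit_network_grid

    def fitter(sub: ExpressionPair):
        return fit_network_grid(sub, alpha1, alpha2, k1, k2, solver_config)

    return _stability_core(
        pair, fitter, k1 * k2, n_runs, seed, apply_change_criteria, t_percentile
    )


def stability_select_separate_grid(
    pair: ExpressionPair,
    alpha1: float = 0.7,
    k1: int = 10,
    n_runs: int = 50,
    seed: int = 0,
    apply_change_criteria: bool = True,
    t_percentile: float = 20.0,
) -> StabilityFrequencies:
    """Per-gene-grid stability selection for the separate-lasso baseline."""
    from .network import fit_separate_lasso_grid

    def fitter(sub: ExpressionPair):
        return fit_separate_lasso_grid(sub, alpha1, k1)

    return _stability_core(
        pair, fitter, k1, n_runs, seed, apply_change_criteria, t_percentile
    )


def stability_select_separate(
    pair: ExpressionPair,
    lam1_values,
    n_runs: int = 50,
    seed: int = 0,
    apply_change_criteria: bool = True,
    t_percentile: float = 20.0,
) -> StabilityFrequencies:
    """Stability selection for the separate-lasso baseline over a lam1 grid.

    Identical resampling and counting scheme to :func:`stability_select`,
    but each refit infers the two networks independently per condition
    (no fusion penalty), which is the benchmark baseline.
    """
    from .network import separate_lasso_pair

    lam1_values = [float(v) for v in lam1_values]
    if not lam1_values:
        raise ValueError("need at least one lam1 value")

    def fitter(sub: ExpressionPair):
        return [separate_lasso_pair(sub, lam1) for lam1 in lam1_values]

    return _stability_core(
        pair, fitter, len(lam1_values), n_runs, seed, apply_change_criteria, t_percentile
    )


def lasso_cv_two_se(
    response: np.ndarray,
    design: np.ndarray,
    lam_values,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """One-condition lasso CV with the two-SE rule; returns the chosen lam.

    ``lam_values`` must be decreasing (largest first).  Folds recenter the
    training split as in :func:`cross_validate`.
    """
    from .solver import lasso_cd

    y = np.asarray(response, dtype=float).ravel()
    z = np.asarray(design, dtype=float)
    n = y.size
    if n < folds:
        raise ValueError("fewer samples than folds")
    lam_values = np.asarray(list(lam_values), dtype=float)
    rng = np.random.default_rng(seed)
    fold_idx = _fold_indices(n, folds, rng)
    fold_pe = np.zeros((folds, lam_values.size))
    for f, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), test)
        mu_z = z[train].mean(axis=0)
        mu_y = y[train].mean()
        z_tr, y_tr = z[train] - mu_z, y[train] - mu_y
        z_te, y_te = z[test] - mu_z, y[test] - mu_y
        b = None
        for k, lam in enumerate(lam_values):
            b = lasso_cd(y_tr, z_tr, float(lam), init=b)
            r = y_te - z_te @ b
            fold_pe[f, k] = r @ r
    pe = fold_pe.mean(axis=0)
    se = fold_pe.std(axis=0, ddof=1) / np.sqrt(folds)
    k_min = int(np.argmin(pe))
    threshold = pe[k_min] + 2.0 * se[k_min]
    lam_opt = lam_values[k_min]
    for k in range(lam_values.size):  # largest first
        if pe[k] <= threshold and lam_values[k] >= lam_values[k_min]:
            lam_opt = lam_values[k]
            break
    return float(lam_opt)


def select_edges_by_threshold(
    freqs: StabilityFrequencies, c: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold frequencies at ``c`` (>= convention) into boolean edge masks."""
    if not 0 < c <= 1:
        raise ValueError("c must lie in (0, 1]")
    return freqs.r >= c, freqs.r_tilde >= c, freqs.delta_r >= c
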