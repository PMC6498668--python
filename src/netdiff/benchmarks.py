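"""End-to-end benchmark protocols on the built-in simulators.

Two studies mirror how the method is validated:

* ``run_linear_benchmark`` — paired sparse regressions (n = 100,
  200 predictors, 20 signals, 10 rewired, noise variance 0.01 by
  default); penalties picked per replicate by five-fold CV with the
  two-SE rule; detection power and FDR pooled over replicates for the
  joint method and a per-condition lasso baseline.
* ``run_network_benchmark`` — paired 50-gene networks (62 edges, 6
  rewired); changed edges ranked by half-sample stability-selection
  frequency; precision-recall of the pooled ranking (area = average
  precision) for the joint method and the lasso baseline.

Both derive all randomness from a single seed and return plain dicts.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluate import pr_aupr_pooled
from .regpath import CV_GRID_DEFAULTS, build_grid
from .selection import (
    cross_validate,
    lasso_cv_two_se,
    stability_select_grid,
    stability_select_separate_grid,
)
from .simulate import LinearSimConfig, NetSimConfig, simulate_linear_pair, simulate_network_pair
from .solver import SolverConfig, lasso_cd, solve_joint

logger = logging.getLogger(__name__)

__all__ = ["run_linear_benchmark", "run_network_benchmark"]


def _pooled_stats(tp: int, fp: int, fn: int) -> dict:
    power = tp / (tp + fn) if tp + fn else 0.0
    fdr = fp / max(1, tp + fp)
    return {"power": power, "fdr": fdr, "tp": tp, "fp": fp, "fn": fn}


def run_linear_benchmark(
    n_replicates: int = 10,
    seed: int = 0,
    sim_config: LinearSimConfig | None = None,
    folds: int = 5,
) -> dict:
    """Power/FDR study on the paired linear-regression simulator.

    Per replicate: generate a problem, pick (lam1, lam2) by five-fold CV
    with the two-SE rule on the standard CV grid, fit the joint solver,
    and fit the per-condition lasso baseline with its own CV (two-SE).
    Detections are nonzero coefficients (nonzero differences for the
    changed entries); counts are pooled over replicates.
    """
    rng = np.random.default_rng(seed)
    a1, a2, k1, k2 = CV_GRID_DEFAULTS
    cv_solver = SolverConfig(tol=1e-5)
    keys = ("beta", "beta_tilde", "delta")
    counts = {m: {k: [0, 0, 0] for k in keys} for m in ("joint", "lasso")}

    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        cfg = sim_config or LinearSimConfig()
        cfg = LinearSimConfig(
            n=cfg.n, p_minus_1=cfg.p_minus_1, n_nonzero=cfg.n_nonzero,
            n_zeroed=cfg.n_zeroed, n_added=cfg.n_added, coef_low=cfg.coef_low,
            coef_high=cfg.coef_high, sigma2=cfg.sigma2, seed=rep_seed,
        )
        design, beta, beta_tilde = simulate_linear_pair(cfg)
        truth = {
            "beta": beta != 0,
            "beta_tilde": beta_tilde != 0,
            "delta": beta != beta_tilde,
        }

        grid = build_grid(design, a1, a2, k1, k2)
        cv = cross_validate(
            design, grid, folds=folds, seed=int(rng.integers(2**31)),
            solver_config=cv_solver,
        )
        res = solve_joint(design, SolverConfig(lam1=cv.lam1_opt, lam2=cv.lam2_opt))
        est_joint = {
            "beta": res.coeffs.beta != 0,
            "beta_tilde": res.coeffs.beta_tilde != 0,
            "delta": res.coeffs.beta != res.coeffs.beta_tilde,
        }

        lam_path_a = 2.0 * np.abs(design.design_a.T @ design.response_a).max() * a1 ** np.arange(k1)
        lam_path_b = 2.0 * np.abs(design.design_b.T @ design.response_b).max() * a1 ** np.arange(k1)
        lam_a = lasso_cv_two_se(
            design.response_a, design.design_a, lam_path_a,
            folds=folds, seed=int(rng.integers(2**31)),
        )
        lam_b = lasso_cv_two_se(
            design.response_b, design.design_b, lam_path_b,
            folds=folds, seed=int(rng.integers(2**31)),
        )
        ba = lasso_cd(design.response_a, design.design_a, lam_a)
        bb = lasso_cd(design.response_b, design.design_b, lam_b)
        est_lasso = {"beta": ba != 0, "beta_tilde": bb != 0, "delta": ba != bb}

        for method, est in (("joint", est_joint), ("lasso", est_lasso)):
            for key in keys:
                c = counts[method][key]
                c[0] += int(np.sum(est[key] & truth[key]))
                c[1] += int(np.sum(est[key] & ~truth[key]))
                c[2] += int(np.sum(~est[key] & truth[key]))

    return {
        "n_replicates": n_replicates,
        **{
            f"{method}_{key}": _pooled_stats(*counts[method][key])
            for method in ("joint", "lasso")
            for key in keys
        },
    }


def run_network_benchmark(
    n_replicates: int = 10,
    seed: int = 0,
    sim_config: NetSimConfig | None = None,
    alpha1: float = 0.7**3,
    alpha2: float = 0.8**3,
    k1: int = 4,
    k2: int = 4,
    n_runs: int = 4,
    solver_config: SolverConfig | None = None,
) -> dict:
    """Changed-edge ranking study on the paired-network simulator.

    Per replicate: simulate a network pair, run stability selection over
    per-gene penalty grids for the joint method and the per-condition
    lasso baseline, and score the change-frequency ranking against the
    truly rewired edges.  The default grid subsamples the standard
    (0.7, 0.8, 10, 10) stability grid's range with coarser spacing, and
    the refits use a capped solver budget — support patterns, not exact
    coefficients, are what is counted.
    """
    rng = np.random.default_rng(seed)
    solver_config = solver_config or SolverConfig(tol=1e-4, max_iter=2500)
    base = sim_config or NetSimConfig()
    per_rep = []
    pooled_j, pooled_s, pooled_truth, n_true = [], [], [], []
    for _ in range(n_replicates):
        cfg = NetSimConfig(
            p=base.p, n_edges=base.n_edges, n_changed=base.n_changed,
            weight_low=base.weight_low, weight_high=base.weight_high,
            n=base.n, sigma2_meas=base.sigma2_meas, seed=int(rng.integers(2**31)),
        )
        pair, truth = simulate_network_pair(cfg)
        off = ~np.eye(pair.n_genes, dtype=bool)
        s1 = int(rng.integers(2**31))
        fj = stability_select_grid(
            pair, alpha1, alpha2, k1, k2, n_runs=n_runs, seed=s1,
            solver_config=solver_config,
        )
        fs = stability_select_separate_grid(pair, alpha1, k1, n_runs=n_runs, seed=s1)
        tr = truth.changed_mask[off]
        nt = int(truth.changed_mask.sum())
        aupr_j = pr_aupr_pooled([fj.delta_r[off]], [tr], [nt]).aupr
        aupr_s = pr_aupr_pooled([fs.delta_r[off]], [tr], [nt]).aupr
        per_rep.append((aupr_j, aupr_s))
        pooled_j.append(fj.delta_r[off])
        pooled_s.append(fs.delta_r[off])
        pooled_truth.append(tr)
        n_true.append(nt)
        logger.info("replicate AUPR joint=%.4f lasso=%.4f", aupr_j, aupr_s)
    return {
        "n_replicates": n_replicates,
        "per_replicate": per_rep,
        "aupr_joint_pooled": pr_aupr_pooled(pooled_j, pooled_truth, n_true).aupr,
        "aupr_separate_pooled": pr_aupr_pooled(pooled_s, pooled_truth, n_true).aupr,
    }
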