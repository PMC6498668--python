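"""Synthetic benchmarks: paired sparse regressions and paired gene networks.

Two generators mirror the study conditions the method is designed for:

* ``simulate_linear_pair`` — a single gene's regression under two
  conditions with i.i.d. standard-normal designs, a sparse coefficient
  vector, and a second vector obtained by rewiring a few entries.
* ``simulate_network_pair`` — a pair of sparse directed networks sharing
  most edges, expression generated through the structural model
  X = E (I - B)^-1 with additive Gaussian measurement noise on top.

The topology generator is a hub-biased stand-in emulating the degree
heterogeneity of curated regulatory networks; an externally produced
adjacency matrix can be supplied instead via ``simulate_network_pair``'s
``adjacency`` hook or the TSV loader in :mod:`netdiff.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import ExpressionPair
from .solver import DesignPair

__all__ = [
    "LinearSimConfig",
    "NetSimConfig",
    "SimTruth",
    "simulate_linear_pair",
    "generate_topology",
    "perturb_topology",
    "simulate_network_pair",
]


@dataclass
class LinearSimConfig:
    """Paired-regression generator settings.

    Defaults reproduce the standard benchmark: n = 100 samples,
    200 predictors of which 20 carry signal, 10 of them rewired (4 zeroed,
    6 added) in the second condition, magnitudes uniform on
    [0.5, 1.5] with random sign, noise variance 0.01.
    """

    n: int = 100
    p_minus_1: int = 200
    n_nonzero: int = 20
    n_zeroed: int = 4
    n_added: int = 6
    coef_low: float = 0.5
    coef_high: float = 1.5
    sigma2: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_nonzero <= self.p_minus_1:
            raise ValueError("n_nonzero must lie in [0, p_minus_1]")
        if self.n_zeroed > self.n_nonzero:
            raise ValueError("cannot zero more entries than are nonzero")
        if self.n_added > self.p_minus_1 - self.n_nonzero:
            raise ValueError("not enough zero entries to add to")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")


@dataclass
class NetSimConfig:
    """Network-pair generator settings.

    Defaults: 50 genes, 62 directed edges, 6 rewired between conditions,
    edge weights uniform on +/-(0, 1], 100 samples, measurement-noise
    variance 0.05.
    """

    p: int = 50
    n_edges: int = 62
    n_changed: int = 6
    weight_low: float = 0.0
    weight_high: float = 1.0
    n: int = 100
    sigma2_meas: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        slots = self.p * (self.p - 1)
        if not 0 <= self.n_edges <= slots:
            raise ValueError("n_edges must lie in [0, p(p-1)]")
        if not 0 <= self.n_changed <= slots:
            raise ValueError("n_changed must lie in [0, p(p-1)]")
        if self.sigma2_meas < 0:
            raise ValueError("sigma2_meas must be nonnegative")


@dataclass
class SimTruth:
    """Ground-truth coefficients/adjacency emitted for evaluation.

    Also carries the generator internals (structural noise ``e``/``e_tilde``
    and noise-free expression ``x``/``x_tilde``) so the structural identity
    X (I - B) = E and the measurement-noise level are auditable.
    """

    b: np.ndarray
    b_tilde: np.ndarray
    a: np.ndarray
    a_tilde: np.ndarray
    e: np.ndarray | None = None
    e_tilde: np.ndarray | None = None
    x: np.ndarray | None = None
    x_tilde: np.ndarray | None = None

    @property
    def changed_mask(self) -> np.ndarray:
        return self.a != self.a_tilde


def _signed_uniform(rng: np.random.Generator, low: float, high: float, size) -> np.ndarray:
    """Uniform magnitude on (low, high] times a random sign (never exactly 0)."""
    mags = high - (high - low) * rng.random(size)  # in (low, high]
    signs = rng.choice([-1.0, 1.0], size=size)
    return mags * signs


def simulate_linear_pair(
    config: LinearSimConfig,
) -> tuple[DesignPair, np.ndarray, np.ndarray]:
    """Generate one paired sparse-regression problem plus its truth.

    Returns a centered DesignPair and the true coefficient vectors
    (beta, beta_tilde); exactly ``n_zeroed + n_added`` entries differ.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p_minus_1
    za = rng.standard_normal((n, p))
    zb = rng.standard_normal((n, p))
    beta = np.zeros(p)
    support = rng.choice(p, size=config.n_nonzero, replace=False)
    beta[support] = _signed_uniform(rng, config.coef_low, config.coef_high, config.n_nonzero)
    beta_tilde = beta.copy()
    zeroed = rng.choice(support, size=config.n_zeroed, replace=False)
    beta_tilde[zeroed] = 0.0
    zeros = np.setdiff1d(np.arange(p), support)
    added = rng.choice(zeros, size=config.n_added, replace=False)
    beta_tilde[added] = _signed_uniform(rng, config.coef_low, config.coef_high, config.n_added)
    sd = np.sqrt(config.sigma2)
    ya = za @ beta + sd * rng.standard_normal(n)
    yb = zb @ beta_tilde + sd * rng.standard_normal(n)
    design = DesignPair.from_raw(ya, za, yb, zb, [f"P{j}" for j in range(p)])
    return design, beta, beta_tilde


def generate_topology(p: int, n_edges: int, seed: int = 0) -> np.ndarray:
    """Directed adjacency with exactly ``n_edges`` edges and hub bias.

    Node regulator/target propensities are drawn from a heavy-tailed
    (Pareto) distribution and each off-diagonal slot (j, i) is weighted by
    the product of j's out-propensity and i's in-propensity; ``n_edges``
    distinct slots are drawn by Gumbel top-k weighted sampling without
    replacement, which yields scale-free-like degree heterogeneity.
    """
    slots = p * (p - 1)
    if not 0 <= n_edges <= slots:
        raise ValueError("infeasible edge count")
    rng = np.random.default_rng(seed)
    w_out = 1.0 + rng.pareto(1.0, size=p)
    w_in = 1.0 + rng.pareto(1.0, size=p)
    weight = np.outer(w_out, w_in)
    np.fill_diagonal(weight, 0.0)
    keys = np.full((p, p), -np.inf)
    off = ~np.eye(p, dtype=bool)
    gumbel = rng.gumbel(size=slots)
    keys[off] = np.log(weight[off]) + gumbel
    flat_order = np.argsort(keys, axis=None)[::-1][:n_edges]
    a = np.zeros((p, p), dtype=int)
    a.flat[flat_order] = 1
    return a


def perturb_topology(a: np.ndarray, n_changed: int, seed: int = 0) -> np.ndarray:
    """Flip ``n_changed`` distinct off-diagonal entries of the adjacency."""
    a = np.asarray(a)
    p = a.shape[0]
    slots = p * (p - 1)
    if not 0 <= n_changed <= slots:
        raise ValueError("infeasible change count")
    rng = np.random.default_rng(seed)
    off_idx = np.flatnonzero(~np.eye(p, dtype=bool).ravel())
    chosen = rng.choice(off_idx, size=n_changed, replace=False)
    a_tilde = a.copy()
    a_tilde.flat[chosen] = 1 - a_tilde.flat[chosen]
    return a_tilde


_SPECTRAL_CAP = 0.95


def simulate_network_pair(
    config: NetSimConfig,
    adjacency: Optional[np.ndarray] = None,
) -> tuple[ExpressionPair, SimTruth]:
    """Generate a paired-network benchmark instance plus its truth.

    Coefficients are signed-uniform on the adjacency support; the second
    network copies the first wherever the topologies agree and draws fresh
    weights (or zeros) where they differ.  Expression follows the
    structural model X = E (I - B)^-1 with standard-normal E, and the
    observed data add N(0, sigma2_meas) measurement noise.  If either
    I - B is too close to singular (spectral radius of B >= 0.95), both
    weight matrices are rescaled by a common factor.
    """
    rng = np.random.default_rng(config.seed)
    p = config.p
    if adjacency is None:
        a = generate_topology(p, config.n_edges, seed=int(rng.integers(2**31)))
    else:
        a = np.asarray(adjacency, dtype=int)
        if a.shape != (p, p):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
    a_tilde = perturb_topology(a, config.n_changed, seed=int(rng.integers(2**31)))

    b = np.zeros((p, p))
    mask = a != 0
    b[mask] = _signed_uniform(rng, config.weight_low, config.weight_high, int(mask.sum()))
    b_tilde = b.copy()
    diff = a_tilde != a
    added = diff & (a_tilde != 0)
    removed = diff & (a_tilde == 0)
    b_tilde[removed] = 0.0
    b_tilde[added] = _signed_uniform(rng, config.weight_low, config.weight_high, int(added.sum()))

    rho = max(_spectral_radius(b), _spectral_radius(b_tilde))
    if rho >= _SPECTRAL_CAP:
        scale = _SPECTRAL_CAP / rho * 0.999
        b *= scale
        b_tilde *= scale

    eye = np.eye(p)
    for m in (eye - b, eye - b_tilde):
        if np.linalg.cond(m) > 1e8:
            raise RuntimeError("structural matrix I - B is near-singular")

    e = rng.standard_normal((config.n, p))
    e_tilde = rng.standard_normal((config.n, p))
    # X (I - B) = E  =>  X = E (I - B)^-1
    x = np.linalg.solve((eye - b).T, e.T).T
    x_tilde = np.linalg.solve((eye - b_tilde).T, e_tilde.T).T
    sd = np.sqrt(config.sigma2_meas)
    y = x + sd * rng.standard_normal((config.n, p))
    y_tilde = x_tilde + sd * rng.standard_normal((config.n, p))
    names = [f"G{j}" for j in range(p)]
    truth = SimTruth(b, b_tilde, a, a_tilde, e, e_tilde, x, x_tilde)
    return ExpressionPair(y, y_tilde, names), truth


def _spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(m)))) if m.size else 0.0
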