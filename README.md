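# netdiff — joint inference of differential gene networks

Gene networks rewire: a transcription factor that drives one set of
targets in healthy tissue may drive a different set in a tumor.  Given
expression matrices for the *same* genes under two conditions, `netdiff`
infers the two condition-specific networks **jointly** and ranks the
edges that changed.  It is aimed at computational biologists analysing
paired designs (tumor/normal, treated/untreated, two developmental
stages) who want the differential network rather than two independently
estimated networks diffed after the fact.

## The model

Each gene *i* is regressed on all other genes (neighborhood selection):

    x_i = X_{-i} β_i + e_i          (condition 1)
    x̃_i = X̃_{-i} β̃_i + ẽ_i        (condition 2)

Nonzero b_ji (entry *j,i* of the coefficient matrix **B**) define a
directed edge *j → i*; the differential network is the support of
ΔB = B − B̃.  Sparsity of each network and sparsity of the *change* are
both encoded in one convex program per gene:

    min  ‖x_i − X_{-i}β‖² + ‖x̃_i − X̃_{-i}β̃‖²
         + λ₁(‖β‖₁ + ‖β̃‖₁) + λ₂‖β − β̃‖₁

The λ₂ term is a fused-lasso penalty that couples each coefficient only
with its counterpart in the other condition, so the proximal operator
decomposes into two-variable fused-lasso problems with a closed-form
solution (fuse the pair toward its midpoint, then soft-threshold).  The
solver is plain proximal gradient with the constant step 1/L,
L = 2(γ + γ̃) from the top eigenvalues of the two Gram matrices, and it
is exact: its λ₂ = 0 solutions match coordinate-descent lasso to 1e-8
and its λ₂ ≥ λ₂max solutions are fused to machine precision.

Around the solver the package provides the full model-selection stack —
λ₁max / λ₂max and geometric penalty grids, five-fold cross-validation
with the two-standard-error rule, and half-sample stability selection
whose edge/change frequencies (r, r̃, Δr) rank edge reliability — plus
the paired simulators (sparse regressions and rewired scale-free-like
networks with expression generated through X = E(I−B)⁻¹), the
changed-edge magnitude criteria, the mean/CoV gene filters used for
real RNA-seq matrices, and precision-recall scoring of changed-edge
rankings.

## Worked example

```python
import numpy as np
from netdiff import (NetSimConfig, SolverConfig, simulate_network_pair,
                     stability_select_grid, infer_network_pair,
                     rank_changed_edges, pr_aupr_pooled)

pair, truth = simulate_network_pair(NetSimConfig(seed=5))   # 50 genes, 62 edges, 6 rewired
freqs = stability_select_grid(pair, alpha1=0.7**3, alpha2=0.8**3, k1=4, k2=4,
                              n_runs=4, seed=5,
                              solver_config=SolverConfig(tol=1e-4, max_iter=2500))
net = infer_network_pair(pair, lam1=60.0, lam2=30.0)
table = rank_changed_edges(freqs, net)
print(table.head(3).to_string())

off = ~np.eye(pair.n_genes, dtype=bool)
res = pr_aupr_pooled([freqs.delta_r[off]], [truth.changed_mask[off]],
                     [int(truth.changed_mask.sum())])
print(f"changed-edge AUPR: {res.aupr:.3f}")
```

Output:

```
  source_gene target_gene         b   b_tilde   delta_b   delta_r
0         G24         G30  0.000000  0.379387 -0.379387  0.453125
1         G44         G10 -0.039185 -0.140017  0.100832  0.421875
2         G30         G24  0.000000  0.342537 -0.342537  0.406250
changed-edge AUPR: 0.418
```

The table ranks candidate changed edges by their stability-selection
change frequency Δr (the fraction of half-sample refits in which the
edge change survived the magnitude criteria), with the coefficients
fitted at one moderate penalty pair alongside.  Here the top candidate
G24 → G30 is a true rewired edge (absent in condition 1, weight 0.59 in
condition 2; its mirrored counterpart G30 → G24 ranks third, the usual
signature of neighborhood regression seeing both endpoints), and the
ranking as a whole retrieves the six planted changes with average
precision 0.418 against 2,450 candidate slots.

A `netdiff` command-line tool wraps the same pipeline for TSV files:
`netdiff simulate-network`, `netdiff infer` (fixed penalties or pooled
CV, optional stability runs and gene filters) and `netdiff evaluate`.

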