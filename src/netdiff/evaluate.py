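"""Scoring of inferred networks against simulator truth.

``detection_power_fdr`` scores a hard support estimate; ``pr_aupr_pooled``
scores a ranked candidate list (stability frequencies) by the
precision-recall curve, pooling candidates across replicates into one
global ranking before computing average precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DetectionStats", "PRResult", "detection_power_fdr", "pr_aupr_pooled"]


@dataclass
class DetectionStats:
    power: float
    fdr: float
    tp: int
    fp: int
    fn: int


@dataclass
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    n_true: int
    n_candidates: int


def detection_power_fdr(estimated: np.ndarray, truth: np.ndarray) -> DetectionStats:
    """Detection power (recall) and false-discovery rate of a support estimate.

    Square matrices are compared off-diagonal only; vectors elementwise.
    An empty detection reports power 0 and FDR 0.
    """
    est = np.asarray(estimated).astype(bool)
    tru = np.asarray(truth).astype(bool)
    if est.shape != tru.shape:
        raise ValueError("shape mismatch between estimate and truth")
    if est.ndim == 2 and est.shape[0] == est.shape[1]:
        off = ~np.eye(est.shape[0], dtype=bool)
        est, tru = est[off], tru[off]
    else:
        est, tru = est.ravel(), tru.ravel()
    tp = int(np.sum(est & tru))
    fp = int(np.sum(est & ~tru))
    fn = int(np.sum(~est & tru))
    power = tp / (tp + fn) if tp + fn > 0 else 0.0
    fdr = fp / max(1, tp + fp)
    return DetectionStats(power=power, fdr=fdr, tp=tp, fp=fp, fn=fn)


def pr_aupr_pooled(
    scores: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    n_true: Sequence[int] | None = None,
) -> PRResult:
    """Pooled precision-recall curve and average precision.

    Each replicate contributes a vector of candidate scores and a matching
    boolean truth vector; ``n_true`` may state the total number of true
    positives per replicate when the candidate list does not exhaust them
    (missed true edges then cap the attainable recall).  All candidates
    are pooled into one descending-score ranking; tied scores are
    processed as one block.  The area is the step-wise average precision
    sum(dR * P) over threshold blocks.
    """
    if len(scores) == 0 or len(scores) != len(truths):
        raise ValueError("need matching, nonempty score/truth sequences")
    pooled_s = np.concatenate([np.asarray(s, dtype=float).ravel() for s in scores])
    pooled_t = np.concatenate([np.asarray(t).astype(bool).ravel() for t in truths])
    if pooled_s.shape != pooled_t.shape:
        raise ValueError("scores and truths must align elementwise")
    if n_true is None:
        total_true = int(pooled_t.sum())
    else:
        if len(n_true) != len(scores):
            raise ValueError("n_true must give one count per replicate")
        total_true = int(sum(n_true))
    if total_true == 0:
        raise ValueError("no true positives anywhere: recall undefined")

    order = np.argsort(-pooled_s, kind="mergesort")
    s_sorted = pooled_s[order]
    t_sorted = pooled_t[order]
    # tie blocks: one threshold per distinct score
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    block_ends = np.append(boundaries, s_sorted.size)
    cum_tp = np.cumsum(t_sorted)
    cum_n = np.arange(1, s_sorted.size + 1)
    tp_at = cum_tp[block_ends - 1]
    n_at = cum_n[block_ends - 1]
    precision = tp_at / n_at
    recall = tp_at / total_true
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    aupr = float(np.sum(d_recall * precision))
    return PRResult(
        precision=precision,
        recall=recall,
        aupr=aupr,
        n_true=total_true,
        n_candidates=int(pooled_s.size),
    )
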