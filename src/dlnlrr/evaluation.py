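"""Clustering agreement metrics: NMI and ARI.

NMI is ``2 MI(M, N) / (H(M) + H(N))`` with natural-log entropies, which
is invariant to the log base.  ARI is the Hubert-Arabie adjusted Rand
index computed from pair counts; unlike NMI it can be negative for
agreement below chance (the degenerate 0/0 cases are defined as 0 for
NMI and 1 for ARI-on-identical-trivial-partitions by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from sklearn.metrics.cluster import contingency_matrix


@dataclass(frozen=True)
class EvaluationScores:
    nmi: float
    ari: float
    contingency: np.ndarray


def _contingency(M, N) -> np.ndarray:
    M = np.asarray(M).ravel()
    N = np.asarray(N).ravel()
    if M.shape != N.shape:
        raise ValueError(f"label length mismatch: {M.shape} vs {N.shape}")
    if M.size == 0:
        raise ValueError("empty labelings")
    return np.asarray(contingency_matrix(M, N), dtype=float)


def nmi(M, N) -> float:
    """Normalized mutual information, arithmetic normalization."""
    C = _contingency(M, N)
    n = C.sum()
    pm = C.sum(axis=1) / n
    pn = C.sum(axis=0) / n
    hm = -np.sum(pm[pm > 0] * np.log(pm[pm > 0]))
    hn = -np.sum(pn[pn > 0] * np.log(pn[pn > 0]))
    pij = C / n
    mask = pij > 0
    outer = pm[:, None] * pn[None, :]
    mi = np.sum(pij[mask] * (np.log(pij[mask]) - np.log(outer[mask])))
    denom = hm + hn
    if denom <= 0 or mi <= 0:
        # a constant partition carries no information: 0/0 -> 0
        return 0.0
    return float(2.0 * mi / denom)


def ari(M, N) -> float:
    """Adjusted Rand index (Hubert-Arabie) from the contingency table."""
    C = _contingency(M, N)
    n = C.sum()
    if n < 2:
        raise ValueError("ARI needs at least two samples")
    sum_ij = comb(C, 2).sum()
    sum_m = comb(C.sum(axis=1), 2).sum()
    sum_n = comb(C.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_m * sum_n / total
    max_index = 0.5 * (sum_m + sum_n)
    if max_index == expected:
        # both partitions trivial (all singletons or one class): define 1
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def evaluate(pred, truth) -> EvaluationScores:
    """NMI and ARI of a predicted labeling against a reference."""
    return EvaluationScores(
        nmi=nmi(truth, pred), ari=ari(truth, pred), contingency=_contingency(truth, pred)
    )
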