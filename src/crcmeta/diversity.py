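"""Alpha diversity, ecological distances and blocked-permutation PERMANOVA.

PERMANOVA follows the classical one-factor partition of a squared-distance
matrix (pseudo-F on SS_between / SS_within); the permutation null shuffles
group labels independently within blocks (cohorts), which is the appropriate
restriction for pooled multi-cohort data with study-level batch structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    n_perm: int
    blocks: list | None = None


def shannon_index(sample) -> float:
    """Shannon diversity H = -sum p ln p (nats) on renormalized positives."""
    x = np.asarray(sample, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("all-zero sample has undefined Shannon index")
    p = pos / pos.sum()
    return float(-np.sum(p * np.log(p)))


def richness(sample, threshold: float = 0.0) -> int:
    """Number of features detected above ``threshold``."""
    x = np.asarray(sample, dtype=float)
    return int(np.sum(x > threshold))


def bray_curtis(a, b) -> float:
    """Bray–Curtis dissimilarity sum|a-b| / sum(a+b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative abundances")
    denom = float(np.sum(a + b))
    if denom == 0:
        raise ValueError("both samples are all-zero")
    return float(np.sum(np.abs(a - b)) / denom)


def bray_curtis_matrix(samples: np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis for a (n_samples, n_features) matrix."""
    X = np.asarray(samples, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / tot, 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def jaccard_matrix(binary: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distance 1 - |A∩B|/|A∪B| on binary presence rows."""
    X = np.asarray(binary, dtype=bool)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        inter = (X[i] & X[i + 1:]).sum(axis=1)
        union = (X[i] | X[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, 1.0 - inter / union, 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def _ss_partition(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Return (SS_total, SS_within) from a squared-distance matrix."""
    n = D2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(D2[iu].sum()) / n
    ss_within = 0.0
    for gval in np.unique(groups):
        idx = np.where(groups == gval)[0]
        if len(idx) < 2:
            continue
        sub = D2[np.ix_(idx, idx)]
        ss_within += float(np.triu(sub, k=1).sum()) / len(idx)
    return ss_total, ss_within


def _pseudo_f(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = D2.shape[0]
    a = len(np.unique(groups))
    ss_total, ss_within = _ss_partition(D2, groups)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, r2


def permanova_blocked(distance_matrix, labels, blocks=None, n_perm: int = 999,
                      seed: int | None = None, rng=None) -> PermanovaResult:
    """One-factor PERMANOVA with label permutations restricted within blocks.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    groups = np.asarray(labels)
    if len(groups) != n:
        raise ValueError("labels length mismatch")
    if len(np.unique(groups)) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if blocks is None:
        blocks_arr = np.zeros(n, dtype=int)
    else:
        blocks_arr = np.asarray(blocks)
        if len(blocks_arr) != n:
            raise ValueError("blocks length mismatch")
    for bval in np.unique(blocks_arr):
        idx = np.where(blocks_arr == bval)[0]
        if len(idx) == 1:
            logger.warning("block %r has a single sample (unpermutable)", bval)

    D2 = D**2
    f_obs, r2 = _pseudo_f(D2, groups)

    if rng is None:
        rng = np.random.default_rng(seed)
    block_idx = [np.where(blocks_arr == b)[0] for b in np.unique(blocks_arr)]
    count = 0
    perm = groups.copy()
    for _ in range(n_perm):
        for idx in block_idx:
            perm[idx] = groups[idx][rng.permutation(len(idx))]
        f_perm, _ = _pseudo_f(D2, perm)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        r2=float(r2), pseudo_f=float(f_obs), p=float(p), n_perm=n_perm,
        blocks=None if blocks is None else list(np.unique(blocks_arr)),
    )
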