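"""Sample-permutation engine shared by the set- and network-based methods.

Significance of a per-set global statistic is estimated by relabeling
samples: the binary group vector is permuted (within blocks for paired
designs), the local statistics are recomputed for every relabeling, and the
p-value is the never-zero counting estimate (b + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from math import comb

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    """How to build the permutation null.

    n_perm random relabelings are drawn (default 1000); with
    ``exhaustive=True`` all distinct relabelings are enumerated instead,
    which makes small-sample p-values exact.  ``paired`` permutes labels
    within blocks only.
    """

    n_perm: int = 1000
    seed: int = 0
    paired: bool = False
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def permutation_pvalue(observed: float, permuted: np.ndarray) -> float:
    """p = (b + 1) / (B + 1) with b = #{permuted >= observed}.

    Strictly positive by construction: a permutation p-value of zero would
    overstate the evidence the resampling can provide.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted values must be non-empty")
    b = int((permuted >= observed).sum())
    return (b + 1) / (permuted.size + 1)


def n_distinct_relabelings(groups: np.ndarray, blocks: np.ndarray | None, paired: bool) -> int:
    groups = np.asarray(groups)
    if paired:
        if blocks is None:
            raise ValueError("paired permutation requires blocks")
        return 2 ** len(np.unique(blocks))
    return comb(len(groups), int((groups == 1).sum()))


def permutation_labelings(
    groups: np.ndarray,
    cfg: PermutationConfig,
    blocks: np.ndarray | None = None,
) -> np.ndarray:
    """Return a (B, n_samples) matrix of 0/1 group labelings.

    Random mode shuffles the observed label vector (or flips case/control
    within each block when paired).  Exhaustive mode enumerates every
    distinct assignment with the observed group sizes (or every within-block
    flip pattern), including the observed labeling itself.
    """
    groups = np.asarray(groups, dtype=int)
    n = len(groups)
    n_case = int((groups == 1).sum())
    n_total = n_distinct_relabelings(groups, blocks, cfg.paired)

    if cfg.exhaustive:
        if cfg.paired:
            uniq = np.unique(blocks)
            out = np.empty((n_total, n), dtype=int)
            for b, flips in enumerate(product((False, True), repeat=len(uniq))):
                lab = groups.copy()
                for blk, flip in zip(uniq, flips):
                    if flip:
                        idx = blocks == blk
                        lab[idx] = 1 - lab[idx]
                out[b] = lab
            return out
        out = np.zeros((n_total, n), dtype=int)
        for b, case_idx in enumerate(combinations(range(n), n_case)):
            out[b, list(case_idx)] = 1
        return out

    if cfg.n_perm > n_total:
        logger.warning(
            "n_perm=%d exceeds the %d distinct relabelings; duplicates permitted",
            cfg.n_perm,
            n_total,
        )
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((cfg.n_perm, n), dtype=int)
    if cfg.paired:
        if blocks is None:
            raise ValueError("paired permutation requires blocks")
        uniq = np.unique(blocks)
        block_idx = [np.flatnonzero(blocks == blk) for blk in uniq]
        for b in range(cfg.n_perm):
            lab = groups.copy()
            flips = rng.integers(0, 2, size=len(uniq))
            for idx, flip in zip(block_idx, flips):
                if flip:
                    lab[idx] = 1 - lab[idx]
            out[b] = lab
    else:
        for b in range(cfg.n_perm):
            out[b] = rng.permutation(groups)
    return out


def batch_pooled_t(values: np.ndarray, labelings: np.ndarray) -> np.ndarray:
    """Pooled-variance t statistics for every gene under every labeling.

    ``values`` is genes x samples, ``labelings`` is B x samples of 0/1;
    returns a (B, genes) matrix.  Group sizes are constant across labelings
    because permutations only rearrange the observed label vector.
    """
    L = np.asarray(labelings, dtype=float)
    n1 = L[0].sum()
    n0 = L.shape[1] - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples per group")
    X = values
    X2 = values**2
    s1 = L @ X.T  # B x genes, sum over case samples
    s0 = (1.0 - L) @ X.T
    q1 = L @ X2.T
    q0 = (1.0 - L) @ X2.T
    m1, m0 = s1 / n1, s0 / n0
    v1 = (q1 - n1 * m1**2) / (n1 - 1)
    v0 = (q0 - n0 * m0**2) / (n0 - 1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    sp2 = np.maximum(sp2, 0.0)  # guard rounding in the sum-of-squares form
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        extreme = np.sign(diff) * np.inf
    t = np.where(se == 0, np.where(diff == 0, 0.0, extreme), t)
    return t


def batch_mean_diff(values: np.ndarray, labelings: np.ndarray) -> np.ndarray:
    """mean(case) - mean(control) per gene for every labeling; (B, genes)."""
    L = np.asarray(labelings, dtype=float)
    n1 = L[0].sum()
    n0 = L.shape[1] - n1
    return (L @ values.T) / n1 - ((1.0 - L) @ values.T) / n0
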