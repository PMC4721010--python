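"""Rank assignment and cross-method rank combination.

Three rank types are supported for a per-set ranking statistic (p-value,
ascending, or score, descending):

* absolute r_A — dense ranks 1..N_D over the distinct statistic values
  (tied sets share a rank; N_D = number of distinct values),
* relative r_R = r_A / N_D * 100,
* competitive r_C — the percentage of gene sets whose statistic is at least
  as extreme as the ranked set's (inclusive of the set itself and its ties,
  so r_C is always strictly positive).

Competitive ranks resolve the distortion absolute/relative ranks suffer when
a coarse-grained ranking (many ties, N_D << N_GS) is compared with a
fine-grained one.  Ranks from several methods are combined per set by sum
(default), mean, median or min, and the combined values re-ranked ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .sbea import EnrichmentRanking

logger = logging.getLogger(__name__)

RANK_TYPES = ("absolute", "relative", "competitive")

COMBINE_FNS: dict[str, Callable[[np.ndarray], float]] = {
    "sum": np.sum,
    "mean": np.mean,
    "median": np.median,
    "min": np.min,
}


def register_combine_fn(name: str, fn: Callable[[np.ndarray], float]) -> None:
    """Plug in a user-defined combination function (vector of ranks -> value)."""
    if name in COMBINE_FNS:
        raise ValueError(f"combination function {name!r} already registered")
    COMBINE_FNS[name] = fn


@dataclass
class RankAssignment:
    set_ids: list[str]
    statistic: np.ndarray
    rank_type: str
    ranks: np.ndarray
    n_distinct: int
    n_sets: int


def assign_ranks(
    stats: np.ndarray,
    order: str = "ascending",
    rank_type: str = "competitive",
    set_ids: list[str] | None = None,
) -> RankAssignment:
    """Assign absolute, relative or competitive ranks to a statistic vector.

    ``order='ascending'`` means smaller is more extreme (p-values);
    ``'descending'`` means larger is more extreme (scores).  Tied values
    receive identical ranks of every type.
    """
    s = np.asarray(stats, dtype=float)
    if s.size == 0:
        raise ValueError("statistic vector must be non-empty")
    if np.isnan(s).any():
        raise ValueError("statistic vector contains NaN")
    if order not in ("ascending", "descending"):
        raise ValueError(f"unknown sort order {order!r}")
    if rank_type not in RANK_TYPES:
        raise ValueError(f"unknown rank type {rank_type!r}")
    key = s if order == "ascending" else -s
    uniq = np.unique(key)  # sorted, most extreme first
    n_distinct = uniq.size
    n_sets = s.size
    absolute = np.searchsorted(uniq, key) + 1  # dense ranks 1..N_D
    if rank_type == "absolute":
        ranks = absolute.astype(float)
    elif rank_type == "relative":
        ranks = absolute / n_distinct * 100.0
    else:  # competitive: inclusive count of at-least-as-extreme sets
        ranks = np.array([(key <= k).sum() for k in key]) / n_sets * 100.0
    if set_ids is None:
        set_ids = [str(i) for i in range(n_sets)]
    return RankAssignment(
        set_ids=list(set_ids),
        statistic=s,
        rank_type=rank_type,
        ranks=ranks,
        n_distinct=int(n_distinct),
        n_sets=int(n_sets),
    )


@dataclass
class CombinedRanking:
    """Cross-method combination of several enrichment rankings.

    ``per_method_ranks`` is sets x methods; ``combined`` the per-set
    combined value; rows are sorted ascending in the combined value with
    ties broken by the best single-method rank, then set id.
    """

    set_ids: list[str]
    method_names: list[str]
    per_method_ranks: np.ndarray
    combined: np.ndarray
    rank_type: str
    combine_fn: str
    support: str

    def position_of(self, set_id: str) -> int:
        return self.set_ids.index(set_id) + 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"set_id": self.set_ids})
        for j, m in enumerate(self.method_names):
            df[f"rank_{m}"] = self.per_method_ranks[:, j]
        df["combined"] = self.combined
        df["final_rank"] = np.arange(1, len(self.set_ids) + 1)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def combine_rankings(
    rankings: list[EnrichmentRanking],
    rank_type: str = "competitive",
    statistic: str = "pval",
    combine_fn: str = "sum",
    support: str = "intersection",
) -> CombinedRanking:
    """Combine several enrichment rankings into one.

    Per-method ranks are assigned by :func:`assign_ranks` on the chosen
    statistic (p-value ascending by default, score descending), then the
    combination function is applied per set across methods.  With
    ``support='intersection'`` only sets present in every ranking are kept;
    with ``'union'`` a set missing from a method contributes that method's
    worst possible rank (N_D absolute, 100 relative/competitive).
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    if statistic not in ("pval", "score"):
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    if support not in ("intersection", "union"):
        raise ValueError(f"unknown support mode {support!r}")
    if combine_fn not in COMBINE_FNS:
        raise ValueError(
            f"unknown combination function {combine_fn!r}; registered: {sorted(COMBINE_FNS)}"
        )
    order = "ascending" if statistic == "pval" else "descending"

    assignments = []
    for r in rankings:
        stats = r.pvals if statistic == "pval" else r.scores
        assignments.append(assign_ranks(stats, order, rank_type, r.set_ids))

    all_ids: list[str] = []
    seen: set[str] = set()
    for r in rankings:
        for s in r.set_ids:
            if s not in seen:
                seen.add(s)
                all_ids.append(s)
    if support == "intersection":
        common = set(rankings[0].set_ids)
        for r in rankings[1:]:
            common &= set(r.set_ids)
        if not common:
            raise ValueError(
                "empty intersection of rankings; re-run with support='union'"
            )
        kept_ids = [s for s in all_ids if s in common]
    else:
        kept_ids = all_ids

    n_missing = 0
    ranks = np.empty((len(kept_ids), len(rankings)))
    positions = np.empty((len(kept_ids), len(rankings)), dtype=int)
    for j, (r, a) in enumerate(zip(rankings, assignments)):
        lookup = dict(zip(a.set_ids, a.ranks))
        pos_lookup = {sid: i + 1 for i, sid in enumerate(r.set_ids)}
        penalty = float(a.n_distinct) if rank_type == "absolute" else 100.0
        for i, sid in enumerate(kept_ids):
            if sid in lookup:
                ranks[i, j] = lookup[sid]
                positions[i, j] = pos_lookup[sid]
            else:
                ranks[i, j] = penalty
                positions[i, j] = len(r.set_ids) + 1
                n_missing += 1
    if n_missing:
        logger.info(
            "%d (set, method) pair(s) missing under union support; worst-rank penalty applied",
            n_missing,
        )

    fn = COMBINE_FNS[combine_fn]
    combined = np.array([fn(ranks[i]) for i in range(len(kept_ids))])
    # tie-break by the best position any single method gave the set, then id
    order_idx = sorted(
        range(len(kept_ids)),
        key=lambda i: (combined[i], positions[i].min(), kept_ids[i]),
    )
    return CombinedRanking(
        set_ids=[kept_ids[i] for i in order_idx],
        method_names=[r.method_name for r in rankings],
        per_method_ranks=ranks[order_idx],
        combined=combined[order_idx],
        rank_type=rank_type,
        combine_fn=combine_fn,
        support=support,
    )
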