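"""Set-based enrichment analysis: ORA, GSEA, SAFE and SAMGS.

ORA tests overrepresentation of significant genes with the hypergeometric
upper tail.  The other three methods share one sample-permutation engine:
a per-gene local statistic (|t|) is recomputed for the observed labels and
for each relabeling, a per-set global statistic aggregates it —

* ``wilcoxon`` (SAFE): rank sum of the member genes' local statistics among
  all measured genes (mid-ranks for ties, one-sided towards large values),
* ``ks`` (GSEA): signed running-sum enrichment score over the list ranked by
  the local statistic,
* ``sum_sq`` (SAMGS): sum of squared per-gene statistics,

and the p-value is the counting estimate (b + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ExpressionDataset, GeneSetCollection
from .diffexp import DEResult, _analysis_matrix, adjust_pvalues
from .permutation import (
    PermutationConfig,
    batch_pooled_t,
    permutation_labelings,
    permutation_pvalue,
)

logger = logging.getLogger(__name__)

SBEA_METHODS = ("ora", "gsea", "safe", "samgs")

#: default size window for sets retained in permutation methods and ORA
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500


@dataclass
class EnrichmentRanking:
    """Per-set score, p-value and BH-adjusted p-value, sorted by significance.

    Rows are ordered by ascending p-value; ties broken by descending score,
    then set id.  ``info`` carries optional per-set columns (e.g. the number
    of induced network edges) aligned with ``set_ids``.
    """

    set_ids: list[str]
    set_sizes: np.ndarray
    scores: np.ndarray
    pvals: np.ndarray
    adj_pvals: np.ndarray
    method_name: str
    info: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        set_ids: list[str],
        set_sizes,
        scores,
        pvals,
        method_name: str,
        info: dict | None = None,
    ) -> "EnrichmentRanking":
        sizes = np.asarray(set_sizes)
        scores = np.asarray(scores, dtype=float)
        pvals = np.asarray(pvals, dtype=float)
        adj = adjust_pvalues(pvals, "BH")
        order = sorted(
            range(len(set_ids)), key=lambda i: (pvals[i], -scores[i], set_ids[i])
        )
        info = info or {}
        return cls(
            set_ids=[set_ids[i] for i in order],
            set_sizes=sizes[order],
            scores=scores[order],
            pvals=pvals[order],
            adj_pvals=adj[order],
            method_name=method_name,
            info={k: np.asarray(v)[order] for k, v in info.items()},
        )

    def __len__(self) -> int:
        return len(self.set_ids)

    def pval_of(self, set_id: str) -> float:
        return float(self.pvals[self.set_ids.index(set_id)])

    def position_of(self, set_id: str) -> int:
        """1-based position of a set in the sorted ranking."""
        return self.set_ids.index(set_id) + 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "set_id": self.set_ids,
                "size": self.set_sizes,
                "score": self.scores,
                "pval": self.pvals,
                "adj_pval": self.adj_pvals,
            }
        )
        for k, v in self.info.items():
            df[k] = v
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def filter_sets(
    gsc: GeneSetCollection,
    measured_genes: list[str],
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> dict[str, list[str]]:
    """Restrict sets to measured genes and apply the size window."""
    measured = set(measured_genes)
    kept: dict[str, list[str]] = {}
    n_dropped = 0
    for sid, genes in gsc.sets.items():
        members = [g for g in genes if g in measured]
        if min_size <= len(members) <= max_size:
            kept[sid] = members
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "dropped %d set(s) outside the size window [%d, %d] after "
            "restriction to measured genes",
            n_dropped,
            min_size,
            max_size,
        )
    return kept


def hypergeom_tail(k, N: int, K: int, n: int):
    """ORA p-value: P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` may be a scalar or array; sf(k - 1) makes the tail inclusive of k.
    """
    return sps.hypergeom.sf(np.asarray(k) - 1, N, K, n)


def ora(
    de: DEResult,
    gsc: GeneSetCollection,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> EnrichmentRanking:
    """Overrepresentation analysis via the hypergeometric upper tail.

    Universe = all genes in ``de``; significant genes are those with
    (adjusted, by default) p-value below ``alpha``.  For a set with n
    measured members of which k are significant, p = P(X >= k) with X
    hypergeometric(N, K, n).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sig_p = de.adj_pval if use_adjusted else de.pval
    significant = {g for g, p in zip(de.gene_ids, sig_p) if p < alpha}
    N = len(de.gene_ids)
    K = len(significant)
    if K == 0:
        logger.warning("no significant genes at alpha=%g: all ORA p-values are 1", alpha)
    kept = filter_sets(gsc, de.gene_ids, min_size, max_size)
    set_ids, sizes, scores, pvals = [], [], [], []
    for sid, members in kept.items():
        n = len(members)
        k = sum(1 for g in members if g in significant)
        p = float(hypergeom_tail(k, N, K, n))
        set_ids.append(sid)
        sizes.append(n)
        scores.append(float(k))
        pvals.append(min(p, 1.0))
    return EnrichmentRanking.build(set_ids, sizes, scores, pvals, "ora")


def gsea_enrichment_score(
    ranked_stats: np.ndarray,
    member_mask: np.ndarray,
    weight_exp: float = 1.0,
) -> float:
    """Signed maximum deviation of the hit/miss running sum.

    ``ranked_stats`` must be sorted in the ranking order (most extreme
    first); hits increment by |stat|^weight_exp normalized over members,
    misses decrement by 1/(N - N_hit).  weight_exp = 0 gives the classic
    Kolmogorov-Smirnov form.
    """
    stats = np.asarray(ranked_stats, dtype=float)
    mask = np.asarray(member_mask, dtype=bool)
    if stats.shape != mask.shape:
        raise ValueError("ranked_stats and member_mask must have equal length")
    n = stats.size
    n_hit = int(mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("enrichment score undefined for empty or full membership")
    w = np.abs(stats) ** weight_exp
    hit_sum = w[mask].sum()
    if hit_sum == 0:
        # all member weights zero (e.g. all-zero statistics): fall back to
        # unweighted increments so the score stays defined
        steps = np.where(mask, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(mask, w / hit_sum, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _batch_es(
    stats: np.ndarray, member_cols: np.ndarray, weight_exp: float
) -> np.ndarray:
    """Enrichment score of one gene set for every permutation row.

    ``stats`` is (B, genes); genes are ranked per row by descending
    statistic (ties broken by gene index for reproducibility).
    """
    B, n = stats.shape
    order = np.argsort(-stats, axis=1, kind="stable")
    sorted_stats = np.take_along_axis(stats, order, axis=1)
    member = np.zeros(n, dtype=bool)
    member[member_cols] = True
    sorted_mask = member[order]
    n_hit = len(member_cols)
    w = np.abs(sorted_stats) ** weight_exp
    w = np.where(sorted_mask, w, 0.0)
    hit_sum = w.sum(axis=1, keepdims=True)
    zero = hit_sum[:, 0] == 0
    if zero.any():
        w[zero] = np.where(sorted_mask[zero], 1.0 / n_hit, 0.0)
        hit_sum = np.where(hit_sum == 0, 1.0, hit_sum)
    steps = w / hit_sum - np.where(sorted_mask, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(B), idx]


def _wilcoxon_rank_sums(local: np.ndarray, member_cols_list: list[np.ndarray]) -> np.ndarray:
    """Member rank sums (mid-ranks) per set for every permutation row."""
    ranks = sps.rankdata(local, axis=1)  # mid-ranks for ties
    return np.column_stack([ranks[:, cols].sum(axis=1) for cols in member_cols_list])


def safe_run(
    data: ExpressionDataset,
    gsc: GeneSetCollection,
    global_stat: str = "wilcoxon",
    cfg: PermutationConfig | None = None,
    weight_exp: float = 0.0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    method_name: str | None = None,
) -> EnrichmentRanking:
    """Permutation-based enrichment with a selectable global statistic.

    The local statistic |t| is recomputed for the observed labels and every
    relabeling; the chosen global statistic is aggregated per set and its
    significance estimated by permutation_pvalue.
    """
    if global_stat not in ("wilcoxon", "ks", "sum_sq"):
        raise ValueError(f"unknown global statistic {global_stat!r}")
    cfg = cfg or PermutationConfig()
    values = _analysis_matrix(data)
    # stable gene order (by id) before ranking, for bit-reproducibility
    gene_order = sorted(range(data.n_genes), key=lambda i: data.gene_ids[i])
    values = values[gene_order]
    gene_ids = [data.gene_ids[i] for i in gene_order]
    gidx = {g: i for i, g in enumerate(gene_ids)}

    kept = filter_sets(gsc, gene_ids, min_size, max_size)
    if not kept:
        raise ValueError("no gene set left after filtering to measured genes")
    member_cols = {
        sid: np.array(sorted(gidx[g] for g in members), dtype=int)
        for sid, members in kept.items()
    }

    # observed labels are computed in the same batch as the relabelings so
    # that mathematically tied global statistics compare as exactly equal
    labelings = permutation_labelings(data.groups, cfg, data.blocks)
    all_labels = np.vstack([data.groups[None, :], labelings])
    all_t = np.abs(batch_pooled_t(values, all_labels))
    observed, permuted = all_t[:1], all_t[1:]

    sids = list(kept)
    cols_list = [member_cols[s] for s in sids]
    if global_stat == "wilcoxon":
        obs_global = _wilcoxon_rank_sums(observed, cols_list)[0]
        perm_global = _wilcoxon_rank_sums(permuted, cols_list)
    elif global_stat == "sum_sq":
        sq_obs, sq_perm = observed**2, permuted**2
        obs_global = np.array([sq_obs[0, c].sum() for c in cols_list])
        perm_global = np.column_stack([sq_perm[:, c].sum(axis=1) for c in cols_list])
    else:  # ks
        obs_global = np.array(
            [_batch_es(observed, c, weight_exp)[0] for c in cols_list]
        )
        perm_global = np.column_stack(
            [_batch_es(permuted, c, weight_exp) for c in cols_list]
        )

    pvals = np.array(
        [
            permutation_pvalue(obs_global[j], perm_global[:, j])
            for j in range(len(sids))
        ]
    )
    sizes = [len(c) for c in cols_list]
    name = method_name or {"wilcoxon": "safe", "ks": "gsea", "sum_sq": "samgs"}[global_stat]
    return EnrichmentRanking.build(sids, sizes, obs_global, pvals, name)


def gsea(
    data: ExpressionDataset,
    gsc: GeneSetCollection,
    cfg: PermutationConfig | None = None,
    weight_exp: float = 1.0,
    **kw,
) -> EnrichmentRanking:
    """GSEA: running-sum enrichment score with sample-permutation p-values.

    weight_exp = 1 is the widely used weighted form; 0 gives the literal
    Kolmogorov-Smirnov statistic.
    """
    return safe_run(
        data, gsc, global_stat="ks", cfg=cfg, weight_exp=weight_exp, method_name="gsea", **kw
    )


def samgs(
    data: ExpressionDataset,
    gsc: GeneSetCollection,
    cfg: PermutationConfig | None = None,
    **kw,
) -> EnrichmentRanking:
    """SAMGS-type enrichment: sum of squared per-gene t-like statistics."""
    return safe_run(data, gsc, global_stat="sum_sq", cfg=cfg, method_name="samgs", **kw)


def safe(
    data: ExpressionDataset,
    gsc: GeneSetCollection,
    cfg: PermutationConfig | None = None,
    **kw,
) -> EnrichmentRanking:
    """SAFE: Wilcoxon rank-sum global statistic under sample permutation."""
    return safe_run(
        data, gsc, global_stat="wilcoxon", cfg=cfg, method_name="safe", **kw
    )
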