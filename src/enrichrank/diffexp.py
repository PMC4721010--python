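"""Per-gene differential expression between two sample groups.

The local statistic is the ordinary pooled-variance two-sample t (or the
paired t on within-block differences).  RNA-seq counts are transformed to
log2(CPM + 0.5) and analysed with the same machinery, so every downstream
enrichment method consumes one t-like statistic regardless of platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import DataType, ExpressionDataset

logger = logging.getLogger(__name__)

ADJUST_METHODS = ("none", "bonferroni", "holm", "BH", "BY")
_SM_METHOD = {"bonferroni": "bonferroni", "holm": "holm", "BH": "fdr_bh", "BY": "fdr_by"}

#: default significance level for calling a gene differentially expressed
DEFAULT_ALPHA = 0.05


@dataclass
class DEResult:
    """Per-gene log2 fold change, t-like statistic, raw and adjusted p-value."""

    gene_ids: list[str]
    log2fc: np.ndarray
    stat: np.ndarray
    pval: np.ndarray
    adj_pval: np.ndarray
    method: str = "pooled_t"
    adjust: str = "BH"

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("log2fc", "stat", "pval", "adj_pval"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per gene")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2fc": self.log2fc,
                "stat": self.stat,
                "pval": self.pval,
                "adj_pval": self.adj_pval,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def log2_cpm(counts: np.ndarray, prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a small prior to keep zeros finite."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    return np.log2(counts / libsize * 1e6 + prior)


def _analysis_matrix(data: ExpressionDataset) -> np.ndarray:
    if data.data_type is DataType.rnaseq:
        return log2_cpm(data.values)
    return data.values


def pooled_t(values: np.ndarray, case: np.ndarray, control: np.ndarray):
    """Row-wise pooled-variance two-sample t statistics and two-sided p-values.

    Zero pooled variance is resolved by convention: equal means give
    (stat 0, p 1); unequal means give +/-inf and the smallest positive float.
    """
    x1, x0 = values[:, case], values[:, control]
    n1, n0 = x1.shape[1], x0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples per group for the pooled t statistic")
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        extreme = np.sign(diff) * np.inf
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d gene(s) with zero pooled variance", int(degenerate.sum()))
        t = np.where(degenerate, np.where(diff == 0, 0.0, extreme), t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(diff == 0, 1.0, np.finfo(float).tiny), p)
    return t, p, diff


def _paired_t(values: np.ndarray, groups: np.ndarray, blocks: np.ndarray):
    uniq = pd.unique(blocks)
    case_col = np.empty(len(uniq), dtype=int)
    ctrl_col = np.empty(len(uniq), dtype=int)
    for b, blk in enumerate(uniq):
        idx = np.flatnonzero(blocks == blk)
        labels = groups[idx]
        if len(idx) != 2 or set(labels) != {0, 1}:
            raise ValueError(
                f"block {blk!r} must contain exactly one case and one control"
            )
        case_col[b] = idx[labels == 1][0]
        ctrl_col[b] = idx[labels == 0][0]
    d = values[:, case_col] - values[:, ctrl_col]
    n = d.shape[1]
    if n < 2:
        raise ValueError("paired t needs >= 2 blocks")
    md = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / se
        extreme = np.sign(md) * np.inf
    degenerate = se == 0
    t = np.where(degenerate, np.where(md == 0, 0.0, extreme), t)
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    p = np.where(degenerate, np.where(md == 0, 1.0, np.finfo(float).tiny), p)
    return t, p, md


def de_statistics(
    data: ExpressionDataset,
    method: str = "pooled_t",
    adjust: str = "BH",
) -> DEResult:
    """Differential expression between the two sample groups.

    log2fc is mean(case) - mean(control) on the log2 scale (log2-CPM for
    count data).  ``method`` is ``pooled_t`` or ``paired_t`` (the latter
    requires a perfect 1:1 block pairing).
    """
    values = _analysis_matrix(data)
    groups = data.groups
    if method == "pooled_t":
        t, p, lfc = pooled_t(values, np.flatnonzero(groups == 1), np.flatnonzero(groups == 0))
    elif method == "paired_t":
        if data.blocks is None:
            raise ValueError("paired_t requires a block annotation")
        t, p, lfc = _paired_t(values, groups, data.blocks)
    else:
        raise ValueError(f"unknown DE method {method!r}")
    adj = adjust_pvalues(p, adjust)
    return DEResult(
        gene_ids=list(data.gene_ids),
        log2fc=lfc,
        stat=t,
        pval=p,
        adj_pval=adj,
        method=method,
        adjust=adjust,
    )


def adjust_pvalues(pvals: np.ndarray, method: str = "BH") -> np.ndarray:
    """Multiple-testing correction; order of the output matches the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in _SM_METHOD:
        raise ValueError(f"unknown correction {method!r}; choose from {ADJUST_METHODS}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=_SM_METHOD[method])[1]


def summarize_probes(
    data: ExpressionDataset,
    probe2gene: dict[str, str],
    mode: str = "mean",
) -> ExpressionDataset:
    """Collapse probe-level rows to gene level.

    mode='mean' averages all probes of a gene per sample; mode='best' keeps
    verbatim the probe that discriminates the most between the two groups
    (largest |pooled t|).  Unmapped probes are dropped with a logged count.
    """
    if not probe2gene:
        raise ValueError("empty probe-to-gene mapping")
    if mode not in ("mean", "best"):
        raise ValueError(f"unknown summarization mode {mode!r}")
    mapped_rows = [i for i, pid in enumerate(data.gene_ids) if pid in probe2gene]
    n_dropped = data.n_genes - len(mapped_rows)
    if n_dropped:
        logger.info("dropping %d unmapped probe(s)", n_dropped)
    if not mapped_rows:
        raise ValueError("no probe maps to a gene")

    by_gene: dict[str, list[int]] = {}
    for i in mapped_rows:
        by_gene.setdefault(probe2gene[data.gene_ids[i]], []).append(i)

    if mode == "best":
        case = np.flatnonzero(data.groups == 1)
        ctrl = np.flatnonzero(data.groups == 0)
        t, _, _ = pooled_t(_analysis_matrix(data), case, ctrl)
        score = np.abs(t)

    rows = []
    gene_ids = []
    for gene, idx in by_gene.items():
        gene_ids.append(gene)
        if mode == "mean" or len(idx) == 1:
            rows.append(data.values[idx].mean(axis=0))
        else:
            best = idx[int(np.argmax(score[idx]))]
            rows.append(data.values[best])
    return ExpressionDataset(
        values=np.vstack(rows),
        gene_ids=gene_ids,
        sample_ids=list(data.sample_ids),
        groups=data.groups.copy(),
        blocks=None if data.blocks is None else data.blocks.copy(),
        data_type=data.data_type,
    )


def quantile_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Between-sample quantile normalization (off by default in the pipeline)."""
    v = data.values
    order = np.argsort(v, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(v.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    mean_sorted = np.sort(v, axis=0).mean(axis=1)
    normalized = mean_sorted[ranks]
    return ExpressionDataset(
        values=normalized,
        gene_ids=list(data.gene_ids),
        sample_ids=list(data.sample_ids),
        groups=data.groups.copy(),
        blocks=None if data.blocks is None else data.blocks.copy(),
        data_type=data.data_type,
    )
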