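"""Network-based enrichment: regulatory-consistency scoring and method plug-ins.

The consistency of a signed regulatory edge with the observed expression
changes of its two genes is scored as

    c(edge) = s * tanh(log2fc_regulator) * tanh(log2fc_target)

with s = +1 for activation and -1 for inhibition, so c lies in [-1, 1] and
saturates for strong fold changes.  A gene set is scored by the sum of
consistencies over its induced edges, with significance from sample-label
permutation (fold changes re-derived for every relabeling).

External methods are attached through :class:`MethodPlugin`: any callable
returning one p-value per gene set participates in ranking, combination and
reporting unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .datamodel import Edge, Effect, ExpressionDataset, GeneSetCollection, RegulatoryNetwork
from .diffexp import DEResult, _analysis_matrix
from .permutation import PermutationConfig, batch_mean_diff, permutation_pvalue, permutation_labelings
from .sbea import DEFAULT_MAX_SET_SIZE, DEFAULT_MIN_SET_SIZE, EnrichmentRanking, filter_sets

logger = logging.getLogger(__name__)

NBEA_METHODS = ("ggea",)

#: plug-in slots reserved for methods this package does not re-implement
RESERVED_PLUGIN_NAMES = frozenset({"spia", "nea", "pathnet"})


def _effect_sign(effect: Effect) -> float:
    return 1.0 if effect is Effect.activation else -1.0


def edge_consistency(de: DEResult, edge: Edge) -> float:
    """Consistency in [-1, 1] of one edge with the observed fold changes."""
    idx = de.gene_index()
    if edge.regulator not in idx or edge.target not in idx:
        raise KeyError("both edge endpoints must be measured")
    f_reg = np.tanh(de.log2fc[idx[edge.regulator]])
    f_tgt = np.tanh(de.log2fc[idx[edge.target]])
    return float(_effect_sign(edge.effect) * f_reg * f_tgt)


def edge_table(de: DEResult, grn: RegulatoryNetwork) -> pd.DataFrame:
    """Per-edge consistency table over edges with both endpoints measured."""
    measured = set(de.gene_ids)
    rows = []
    for e in grn.edges:
        if e.regulator in measured and e.target in measured:
            rows.append(
                {
                    "regulator": e.regulator,
                    "target": e.target,
                    "effect": e.effect.symbol,
                    "consistency": edge_consistency(de, e),
                }
            )
    return pd.DataFrame(rows, columns=["regulator", "target", "effect", "consistency"])


def _induced_edges(
    members: set[str], measured: set[str], grn: RegulatoryNetwork, edges_mode: str
) -> list[Edge]:
    out = []
    for e in grn.edges:
        if e.regulator not in measured or e.target not in measured:
            continue
        in_reg, in_tgt = e.regulator in members, e.target in members
        hit = (in_reg and in_tgt) if edges_mode == "within" else (in_reg or in_tgt)
        if hit:
            out.append(e)
    return out


def ggea(
    data: ExpressionDataset,
    gsc: GeneSetCollection,
    grn: RegulatoryNetwork,
    cfg: PermutationConfig | None = None,
    edges: str = "adjacent",
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> EnrichmentRanking:
    """Gene-graph enrichment: per-set sum of induced-edge consistencies.

    ``edges='adjacent'`` (default) induces every edge with at least one
    endpoint in the set, so regulators outside the set still contribute
    mechanism; ``'within'`` requires both endpoints.  The p-value permutes
    sample labels and re-derives fold changes for the raw score; the
    normalized score (raw / #edges, in [-1, 1]) is reported alongside.
    Sets without induced edges get score 0 and p = 1, flagged in the output.
    """
    if len(grn) == 0:
        raise ValueError("regulatory network is empty")
    if edges not in ("adjacent", "within"):
        raise ValueError(f"unknown edge induction mode {edges!r}")
    cfg = cfg or PermutationConfig()
    values = _analysis_matrix(data)
    gidx = data.gene_index()
    measured = set(data.gene_ids)

    kept = filter_sets(gsc, data.gene_ids, min_size, max_size)
    if not kept:
        raise ValueError("no gene set left after filtering to measured genes")

    induced = {
        sid: _induced_edges(set(members), measured, grn, edges)
        for sid, members in kept.items()
    }

    # one batch for observed + relabelings keeps tied scores exactly equal
    labelings = permutation_labelings(data.groups, cfg, data.blocks)
    all_f = np.tanh(
        batch_mean_diff(values, np.vstack([data.groups[None, :], labelings]))
    )
    obs_f, perm_f = all_f[0], all_f[1:]

    set_ids, sizes, raw_scores, norm_scores, pvals, n_edges_col = [], [], [], [], [], []
    for sid, members in kept.items():
        edges_s = induced[sid]
        set_ids.append(sid)
        sizes.append(len(members))
        n_edges_col.append(len(edges_s))
        if not edges_s:
            raw_scores.append(0.0)
            norm_scores.append(0.0)
            pvals.append(1.0)
            continue
        reg_idx = np.array([gidx[e.regulator] for e in edges_s])
        tgt_idx = np.array([gidx[e.target] for e in edges_s])
        signs = np.array([_effect_sign(e.effect) for e in edges_s])
        raw = float((signs * obs_f[reg_idx] * obs_f[tgt_idx]).sum())
        perm_raw = (signs * perm_f[:, reg_idx] * perm_f[:, tgt_idx]).sum(axis=1)
        raw_scores.append(raw)
        norm_scores.append(raw / len(edges_s))
        pvals.append(permutation_pvalue(raw, perm_raw))
    if not any(n_edges_col):
        logger.warning("no gene set has induced network edges")
    return EnrichmentRanking.build(
        set_ids,
        sizes,
        raw_scores,
        pvals,
        "ggea",
        info={
            "norm_score": np.array(norm_scores),
            "n_edges": np.array(n_edges_col),
            "no_edges": np.array([n == 0 for n in n_edges_col]),
        },
    )


@dataclass
class MethodPlugin:
    """A user-supplied enrichment method.

    ``func(data, gsc, alpha, grn=None)`` must return one p-value in [0, 1]
    per gene set, in collection order.
    """

    name: str
    func: Callable
    requires_network: bool = False


def run_plugin(
    plugin: MethodPlugin,
    data: ExpressionDataset,
    gsc: GeneSetCollection,
    alpha: float = 0.05,
    grn: RegulatoryNetwork | None = None,
) -> EnrichmentRanking:
    """Execute a plug-in and wrap its p-vector into a ranking (score = -p)."""
    if plugin.requires_network and grn is None:
        raise ValueError(f"plug-in {plugin.name!r} requires a regulatory network")
    if plugin.requires_network:
        pvec = plugin.func(data, gsc, alpha, grn=grn)
    else:
        pvec = plugin.func(data, gsc, alpha)
    p = np.asarray(pvec, dtype=float)
    sids = gsc.set_ids()
    if p.shape != (len(sids),):
        raise ValueError(
            f"plug-in {plugin.name!r} returned {p.size} value(s) for {len(sids)} gene sets"
        )
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError(f"plug-in {plugin.name!r} returned p-values outside [0, 1]")
    measured = set(data.gene_ids)
    sizes = [len([g for g in gsc[s] if g in measured]) for s in sids]
    return EnrichmentRanking.build(sids, sizes, -p, p, plugin.name)


class PluginRegistry:
    """Named registry of plug-in methods; reserved slots cannot be overridden."""

    def __init__(self) -> None:
        self._plugins: dict[str, MethodPlugin] = {}

    def register(self, plugin: MethodPlugin) -> None:
        if plugin.name in self._plugins:
            raise ValueError(f"plug-in {plugin.name!r} already registered")
        self._plugins[plugin.name] = plugin

    def get(self, name: str) -> MethodPlugin:
        if name in RESERVED_PLUGIN_NAMES and name not in self._plugins:
            raise KeyError(
                f"{name!r} is a reserved plug-in slot; register an implementation first"
            )
        return self._plugins[name]

    def __contains__(self, name: str) -> bool:
        return name in self._plugins
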