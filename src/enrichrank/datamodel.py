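"""Core data containers: expression matrix, gene set collection, regulatory network.

Gene identifiers are opaque, case-sensitive strings throughout; no species or
probe annotation mapping is attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class DataType(str, Enum):
    microarray = "microarray"
    rnaseq = "rnaseq"


class Effect(str, Enum):
    activation = "activation"
    inhibition = "inhibition"

    @classmethod
    def from_symbol(cls, sym: str) -> "Effect":
        if sym == "+":
            return cls.activation
        if sym == "-":
            return cls.inhibition
        raise FormatError(f"unknown effect symbol {sym!r}; expected '+' or '-'")

    @property
    def symbol(self) -> str:
        return "+" if self is Effect.activation else "-"


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with a binary group annotation.

    ``values`` holds log2 intensities for ``data_type='microarray'`` and
    non-negative integer read counts for ``data_type='rnaseq'``.  ``groups``
    is the binary classification vector (0 = control, 1 = case); ``blocks``
    optionally pairs samples (one case and one control per block).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    groups: np.ndarray
    blocks: np.ndarray | None = None
    data_type: DataType = DataType.microarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        self.data_type = DataType(self.data_type)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match number of columns")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.groups.shape != (n_samples,):
            raise ValueError("groups must have one label per sample")
        if not set(np.unique(self.groups)) <= {0, 1}:
            raise ValueError("groups must be coded 0 (control) / 1 (case)")
        if not ((self.groups == 0).any() and (self.groups == 1).any()):
            raise ValueError("each of the two groups needs at least one sample")
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks)
            if self.blocks.shape != (n_samples,):
                raise ValueError("blocks must have one label per sample")
        if self.data_type is DataType.rnaseq and (self.values < 0).any():
            raise ValueError("rnaseq values must be non-negative counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneSetCollection:
    """Ordered mapping of set id -> member gene ids, plus free-text descriptions.

    Within-set duplicates are removed (first occurrence kept); set order and
    within-set gene order are otherwise preserved.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        deduped: dict[str, list[str]] = {}
        for sid, genes in self.sets.items():
            seen: set[str] = set()
            uniq = [g for g in genes if not (g in seen or seen.add(g))]
            if not uniq:
                raise ValueError(f"gene set {sid!r} is empty")
            deduped[sid] = uniq
        self.sets = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def set_ids(self) -> list[str]:
        return list(self.sets)

    def subset(self, set_ids: list[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={s: list(self.sets[s]) for s in set_ids},
            descriptions={s: self.descriptions.get(s, "") for s in set_ids},
        )


@dataclass(frozen=True)
class Edge:
    regulator: str
    target: str
    effect: Effect


@dataclass
class RegulatoryNetwork:
    """Directed signed edges (activation/inhibition) over gene identifiers.

    Exact duplicate triples are collapsed; a pair annotated with both effects
    keeps both edges (conflicting evidence is real in curated networks).
    """

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[Edge] = set()
        uniq: list[Edge] = []
        for e in self.edges:
            if e not in seen:
                seen.add(e)
                uniq.append(e)
        self.edges = uniq

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def flipped(self) -> "RegulatoryNetwork":
        """Network with every edge effect inverted (used in consistency checks)."""
        inv = {Effect.activation: Effect.inhibition, Effect.inhibition: Effect.activation}
        return RegulatoryNetwork([Edge(e.regulator, e.target, inv[e.effect]) for e in self.edges])
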