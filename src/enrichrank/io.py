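"""Readers and writers for the plain-text formats the tool touches.

Dialects:

* GMT — tab-separated ``set_id<TAB>description<TAB>gene...``, one set per line.
* Network TSV — ``regulator<TAB>target<TAB>{+,-}``; ``#`` comment lines skipped.
* Expression TSV — header ``gene_id<TAB>s1<TAB>...``, one numeric row per gene.
* Groups TSV — ``sample_id<TAB>{0,1}[<TAB>block]``; its row order defines the
  sample order of the resulting dataset, so results never depend on the column
  order of the matrix file.

Missing values are not supported: a non-numeric cell (including ``NA``) is a
format error with coordinates.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DataType,
    Edge,
    Effect,
    ExpressionDataset,
    FormatError,
    GeneSetCollection,
    RegulatoryNetwork,
)

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Order of sets is the line order; genes are deduplicated within each set.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            sid, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {sid!r} has no genes")
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = genes
            descriptions[sid] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, genes in gsc.sets.items():
            desc = gsc.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a 3-column signed-edge TSV (regulator, target, {+,-})."""
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: network line needs exactly 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            reg, tgt, sym = fields
            try:
                effect = Effect.from_symbol(sym)
            except FormatError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
            edges.append(Edge(reg, tgt, effect))
    return RegulatoryNetwork(edges)


def write_network(grn: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in grn.edges:
            fh.write(f"{e.regulator}\t{e.target}\t{e.effect.symbol}\n")


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    data_type: str | DataType = DataType.microarray,
) -> ExpressionDataset:
    """Read an expression matrix plus its sample classification file.

    The groups file is the source of sample order: matrix columns are
    reordered to match it, making every downstream statistic invariant to
    column permutations of the matrix file.
    """
    sample_ids: list[str] = []
    groups: list[int] = []
    blocks: list[str] = []
    has_blocks = False
    with open(groups_path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) not in (2, 3):
                raise FormatError(
                    f"{groups_path}:{lineno}: expected sample_id<TAB>group[<TAB>block]"
                )
            sid, grp = row[0], row[1]
            if grp not in ("0", "1"):
                raise FormatError(
                    f"{groups_path}:{lineno}: group label must be 0 or 1, got {grp!r}"
                )
            sample_ids.append(sid)
            groups.append(int(grp))
            if len(row) == 3:
                has_blocks = True
                blocks.append(row[2])
            else:
                blocks.append("")
    if has_blocks and any(b == "" for b in blocks):
        raise FormatError(f"{groups_path}: block column present for some samples only")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{groups_path}: duplicate sample ids")

    df = pd.read_csv(matrix_path, sep="\t", header=0, index_col=0, dtype=str)
    matrix_samples = list(df.columns)
    missing = sorted(set(sample_ids) - set(matrix_samples))
    extra = sorted(set(matrix_samples) - set(sample_ids))
    if missing or extra:
        raise FormatError(
            f"sample mismatch between {matrix_path} and {groups_path}: "
            f"missing from matrix: {missing}; missing from groups file: {extra}"
        )
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{matrix_path}: duplicate gene ids: {dupes[:5]}")

    df = df[sample_ids]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{matrix_path}: non-numeric cell {cell!r} at gene "
                    f"{gene_ids[i]!r}, sample {col!r}"
                ) from None
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise FormatError(
            f"{matrix_path}: missing value at gene {gene_ids[i]!r}, "
            f"sample {df.columns[j]!r} (NA not supported)"
        )

    return ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        groups=np.array(groups, dtype=int),
        blocks=np.array(blocks) if has_blocks else None,
        data_type=DataType(data_type),
    )


def write_expression(data: ExpressionDataset, matrix_path: str | Path, groups_path: str | Path) -> None:
    df = pd.DataFrame(data.values, index=pd.Index(data.gene_ids, name="gene_id"), columns=data.sample_ids)
    df.to_csv(matrix_path, sep="\t", float_format="%.6g")
    with open(groups_path, "w", encoding="utf-8") as fh:
        for j, sid in enumerate(data.sample_ids):
            row = [sid, str(int(data.groups[j]))]
            if data.blocks is not None:
                row.append(str(data.blocks[j]))
            fh.write("\t".join(row) + "\n")
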