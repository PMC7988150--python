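"""Readers and writers for the pipeline's plain-text formats.

Canonical dialects:

* expression matrices — TSV, first column gene ID, header row of sample
  or time labels, ``#``-prefixed comment lines skipped;
* gene sets — one gene ID per line;
* networks — GraphML with cluster membership and vertex weights as node
  attributes (stands in for interactive network visualization);
* result reports — JSON.

Parsing is strict: ragged rows, non-numeric or negative values and
duplicate identifiers raise :class:`ParseError` with the offending line
number.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .containers import GeneSet, GroupedMatrix, TimeCourseMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_gene_set",
    "write_gene_set",
    "read_group_map",
    "write_graphml",
]


class ParseError(ValueError):
    """A file violates its format contract; message carries the line number."""


def _parse_tsv(path: str | Path) -> tuple[list[str], list[str], list[list[float]]]:
    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts[1:]]
                if not header:
                    raise ParseError(f"{path}: line {lineno}: header has no sample columns")
                continue
            gene = parts[0].strip()
            if not gene:
                raise ParseError(f"{path}: line {lineno}: empty gene ID")
            if gene in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene ID {gene!r}")
            if len(parts) - 1 != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} values, got {len(parts) - 1}"
                )
            vals: list[float] = []
            for col, token in zip(header, parts[1:]):
                try:
                    v = float(token)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric value {token!r} in column {col!r}"
                    ) from None
                if math.isnan(v) or math.isinf(v):
                    raise ParseError(f"{path}: line {lineno}: non-finite value in column {col!r}")
                if v < 0:
                    raise ParseError(
                        f"{path}: line {lineno}: negative value {token} in column {col!r}"
                    )
                vals.append(v)
            seen.add(gene)
            gene_ids.append(gene)
            rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty file")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return header, gene_ids, rows


def read_matrix(
    path: str | Path,
    kind: str = "timecourse",
    group_map: Mapping[str, str] | None = None,
    levels: tuple[str, str] | None = None,
) -> TimeCourseMatrix | GroupedMatrix:
    """Read a validated expression matrix from TSV.

    Parameters
    ----------
    kind
        ``"timecourse"`` (columns are hours) or ``"grouped"`` (columns are
        sample IDs; ``group_map`` is then required).
    group_map
        Sample ID -> group label, for ``kind="grouped"``.
    levels
        Optional (A, B) ordering of the two group labels.
    """
    header, gene_ids, rows = _parse_tsv(path)
    df = pd.DataFrame(rows, index=gene_ids, columns=header)
    try:
        if kind == "timecourse":
            hours = []
            for col in header:
                token = col[:-1] if col.lower().endswith("h") else col
                try:
                    hours.append(float(token))
                except ValueError:
                    raise ParseError(f"{path}: time-point column {col!r} is not numeric hours")
            df.columns = hours
            return TimeCourseMatrix(df)
        if kind == "grouped":
            if group_map is None:
                raise ValueError("group_map is required for kind='grouped'")
            return GroupedMatrix(df, group_of=group_map, levels=levels)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(m: TimeCourseMatrix | GroupedMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (values formatted with %.10g)."""
    if isinstance(m, TimeCourseMatrix):
        cols = [f"{h:g}" for h in m.timepoints_h]
    else:
        cols = m.sample_ids
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cols) + "\n")
        for gene, row in zip(m.data.index, m.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sample ID and group label."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 'sample<TAB>group'")
            if parts[0] in out:
                raise ParseError(f"{path}: line {lineno}: duplicate sample {parts[0]!r}")
            out[parts[0]] = parts[1]
    if not out:
        raise ParseError(f"{path}: empty group map")
    return out


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-ID-per-line gene set; duplicates are dropped with a warning."""
    members: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            gene = raw.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene in seen:
                log.warning("%s: duplicated gene ID %r dropped", path, gene)
                continue
            seen.add(gene)
            members.append(gene)
    if not members:
        raise ParseError(f"{path}: empty gene-set file")
    return GeneSet(name=name or Path(path).stem, members=frozenset(members))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gs.members):
            fh.write(gene + "\n")


def write_graphml(graph: nx.Graph, clusters: Iterable | None, path: str | Path,
                  weights: Mapping[str, float] | None = None) -> None:
    """Export a co-expression graph with cluster membership annotations.

    Node attributes: ``cluster`` (1-based index into the cluster list, 0 =
    unclustered), ``direction`` (cluster direction label or ``""``) and
    ``weight`` (MCODE vertex weight when supplied). Edge attributes ``r``
    and ``p`` are preserved from the input graph.
    """
    g = graph.copy()
    membership: dict[str, int] = {}
    direction: dict[str, str] = {}
    for i, cluster in enumerate(clusters or [], start=1):
        for gene in cluster.members:
            membership[gene] = i
            direction[gene] = cluster.direction or ""
    for node in g.nodes:
        g.nodes[node]["cluster"] = membership.get(node, 0)
        g.nodes[node]["direction"] = direction.get(node, "")
        if weights is not None:
            g.nodes[node]["weight"] = float(weights.get(node, 0.0))
    nx.write_graphml(g, path)
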