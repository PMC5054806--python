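"""Readers and writers: SIF networks, edge-weight tables, result tables.

SIF (Cytoscape Simple Interaction Format) is line oriented::

    source  interactionType  target [target2 ...]

A single-token line declares an isolated node; a line with k targets
expands to k edges sharing the interaction label.  Both tab- and
space-delimited files are accepted (tokenisation is whitespace based, as
Cytoscape's own parser allows either), which implies node identifiers
cannot contain whitespace.  SIF carries no direction semantics: whether a
file is read as directed is a load-time flag.

Two weight dialects are supported:

* ``tsv3`` — three columns ``source  target  weight``, optional header
  (detected by a non-numeric third field on the first line);
* ``cytoscape_ea`` — a Cytoscape edge-attribute file: a header line naming
  the attribute, then ``source (label) target = value`` lines.
"""

from __future__ import annotations

import re
from typing import IO, Iterable, Union

from .errors import (
    SifParseError,
    WeightAttributeMismatchError,
    WeightParseError,
)
from .graph import Graph, WeightMap

TextSource = Union[str, IO[str], Iterable[str]]


def _iter_lines(stream: TextSource) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream


def read_sif(stream: TextSource, directed: bool = False) -> Graph:
    """Parse a SIF stream (or string) into a :class:`~spnet.graph.Graph`.

    A line with exactly two tokens is malformed (neither an isolated node
    nor a complete interaction) and raises :class:`SifParseError` naming
    the line number.  An empty stream yields an empty graph.
    """
    nodes: list[str] = []
    edges: list[tuple[str, str, str]] = []
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if len(tokens) == 1:
            nodes.append(tokens[0])
        elif len(tokens) == 2:
            raise SifParseError(
                lineno,
                f"2 tokens ({raw.strip()!r}): expected 1 (isolated node) or >= 3 "
                "(source interaction target ...)",
            )
        else:
            src, label, *targets = tokens
            for t in targets:
                edges.append((src, t, label))
    return Graph(nodes, edges, directed=directed)


def write_sif(graph: Graph, stream: IO[str]) -> None:
    """Emit a graph as SIF: one line per edge, one token per isolated node.

    Output is deterministically sorted, so identical graphs serialise to
    identical bytes; ``read_sif(write_sif(g))`` reproduces ``g`` (weights
    are not part of SIF and are dropped).
    """
    for u, v, label in sorted(graph.edges):
        stream.write(f"{u}\t{label}\t{v}\n")
    for node in sorted(graph.isolated_nodes()):
        stream.write(f"{node}\n")


_EA_LINE = re.compile(r"^(\S+)\s+\((.*)\)\s+(\S+)\s*=\s*(\S+)$")


def read_weights(
    stream: TextSource, attribute_name: str, dialect: str = "tsv3"
) -> WeightMap:
    """Parse an edge-weight file into a :class:`~spnet.graph.WeightMap`.

    Negative weights are accepted.  Non-numeric weight values raise
    :class:`WeightParseError` with the line number; in the
    ``cytoscape_ea`` dialect a header naming a different attribute raises
    :class:`WeightAttributeMismatchError`.  Duplicate entries for one edge
    keep the minimum value (a warning is logged at attachment).
    """
    if dialect == "tsv3":
        return _read_tsv3(stream, attribute_name)
    if dialect == "cytoscape_ea":
        return _read_cytoscape_ea(stream, attribute_name)
    raise ValueError(f"unknown weight dialect: {dialect!r}")


def _parse_value(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise WeightParseError(lineno, f"non-numeric weight value {token!r}") from None


def _store(entries: dict, key, value):
    if key in entries:
        entries[key] = min(entries[key], value)
    else:
        entries[key] = value


def _read_tsv3(stream: TextSource, attribute_name: str) -> WeightMap:
    entries: dict[tuple[str, str], float] = {}
    first_data_line = True
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        fields = raw.split()
        if not fields:
            continue
        if len(fields) != 3:
            raise WeightParseError(
                lineno, f"expected 3 columns (source target weight), got {len(fields)}"
            )
        if first_data_line:
            first_data_line = False
            try:
                float(fields[2])
            except ValueError:
                continue  # header row
        _store(entries, (fields[0], fields[1]), _parse_value(fields[2], lineno))
    return WeightMap(attribute_name, entries)


def _read_cytoscape_ea(stream: TextSource, attribute_name: str) -> WeightMap:
    entries: dict[tuple[str, str], float] = {}
    header_seen = False
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        if not header_seen:
            header_seen = True
            # header is the attribute name, possibly with a class hint
            found = line.split()[0]
            if found != attribute_name:
                raise WeightAttributeMismatchError(attribute_name, found)
            continue
        m = _EA_LINE.match(line)
        if not m:
            raise WeightParseError(
                lineno, f"expected 'source (label) target = value', got {line!r}"
            )
        src, _label, tgt, value = m.groups()
        _store(entries, (src, tgt), _parse_value(value, lineno))
    return WeightMap(attribute_name, entries)


def _format_size(value, weighted: bool) -> str:
    if not weighted:
        return str(int(value))
    return f"{float(value):.9g}"


def write_path_table(pathset, stream: IO[str]) -> None:
    """Write a result table: one row per direction-annotated path listing.

    Columns are exactly ``source  target  size  path``; ``size`` is the hop
    count, or the total weight in weighted mode, and ``path`` joins node
    identifiers with ``|``.  Rows are sorted by (source, target, node
    sequence) so output is byte-deterministic.
    """
    stream.write("source\ttarget\tsize\tpath\n")
    records = sorted(pathset.records, key=lambda r: (r.source, r.target, r.path.nodes))
    for rec in records:
        size = rec.path.total_weight if pathset.weighted else rec.path.hops
        stream.write(
            f"{rec.source}\t{rec.target}\t{_format_size(size, pathset.weighted)}\t"
            + "|".join(rec.path.nodes)
            + "\n"
        )


def write_stats_table(stats, length_table, stream: IO[str], weighted: bool = False) -> None:
    """Write the statistics panel as key/value TSV rows.

    The grouped path-length table is appended as ``paths_of_size_<k>``
    rows, sorted by size.  An undefined average (no paths) is written as
    ``NA``.
    """
    if stats.average_path_length is None:
        avg = "NA"
    else:
        avg = f"{float(stats.average_path_length):.9g}"
    stream.write(f"average_path_length\t{avg}\n")
    stream.write(f"unique_paths\t{stats.unique_paths}\n")
    stream.write(f"expected_paths\t{stats.expected_paths}\n")
    stream.write(f"connected\t{stats.connected}\n")
    for size in sorted(length_table):
        stream.write(
            f"paths_of_size_{_format_size(size, weighted)}\t{length_table[size]}\n"
        )
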