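"""Read, validate, filter and weight a functional gene network.

The input is a 3-column tab-separated edge list (geneA, geneB, functional
linkage score).  Linkage scores are confidence-like values in (0, 1] where
higher means a stronger functional association between the two genes.  The
analysis network is obtained by keeping only the top fraction of edges by
score (1% by default) and converting each retained score into a
shortest-path distance via its reciprocal: weight = 1 / score, so strongly
linked genes are close.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import networkx as nx

from .errors import FormatError, ParameterError, ValidationError

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected network edge with its functional linkage score."""

    gene_a: str
    gene_b: str
    score: float

    def key(self) -> tuple[str, str]:
        """Unordered endpoint pair, canonically sorted."""
        return (self.gene_a, self.gene_b) if self.gene_a <= self.gene_b else (self.gene_b, self.gene_a)


def _normalize_symbol(raw: str) -> str:
    return raw.strip().upper()


def _open_maybe(source: Union[PathLike, TextIO]) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=None), True
    return source, False


def read_edge_list(source: Union[PathLike, TextIO]) -> list[EdgeRecord]:
    """Parse a 3-column TSV edge list into :class:`EdgeRecord` objects.

    Gene symbols are stripped and uppercased.  An optional header line
    (detected by a non-numeric third field on the first non-empty line) is
    skipped.  Self-loops are dropped and duplicate unordered pairs are
    collapsed keeping the maximum score; both events are logged with counts.

    Raises
    ------
    FormatError
        If a data row has fewer than 3 fields or a non-header row carries an
        unparseable score.  The error message names the 1-based line number.
    ValidationError
        If the file contains no data rows.
    """
    stream, owned = _open_maybe(source)
    best: dict[tuple[str, str], EdgeRecord] = {}
    n_self_loops = 0
    n_duplicates = 0
    try:
        first_data_seen = False
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            try:
                score = float(fields[2])
            except ValueError:
                if not first_data_seen:
                    # header row: third field non-numeric before any data
                    continue
                raise FormatError(f"line {lineno}: unparseable score {fields[2]!r}") from None
            if not math.isfinite(score) or score <= 0:
                raise ValidationError(
                    f"line {lineno}: score must be finite and > 0, got {score!r}"
                )
            first_data_seen = True
            a, b = _normalize_symbol(fields[0]), _normalize_symbol(fields[1])
            if not a or not b:
                raise FormatError(f"line {lineno}: empty gene symbol")
            if a == b:
                n_self_loops += 1
                continue
            rec = EdgeRecord(a, b, score)
            key = rec.key()
            if key in best:
                n_duplicates += 1
                if score > best[key].score:
                    best[key] = EdgeRecord(key[0], key[1], score)
            else:
                best[key] = EdgeRecord(key[0], key[1], score)
    finally:
        if owned:
            stream.close()
    if n_self_loops:
        log.info("dropped %d self-loop edge(s)", n_self_loops)
    if n_duplicates:
        log.info("collapsed %d duplicate pair(s), keeping the maximum score", n_duplicates)
    if not best:
        raise ValidationError("edge list contains no data rows")
    return list(best.values())


def filter_top_edges(edges: Sequence[EdgeRecord], fraction: float = 0.01) -> list[EdgeRecord]:
    """Keep the top ``fraction`` of edges by linkage score.

    With ``m`` edges and ``c = ceil(fraction * m)``, every edge whose score
    is >= the c-th largest score is retained, so ties at the cutoff are all
    kept and the result may exceed ``c``.  The default fraction of 0.01
    keeps the top 1% of edges.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    if not edges:
        raise ParameterError("edge list is empty")
    m = len(edges)
    c = math.ceil(fraction * m)
    cutoff = sorted((e.score for e in edges), reverse=True)[c - 1]
    kept = [e for e in edges if e.score >= cutoff]
    log.info("edge filter: kept %d of %d edges (fraction=%g, cutoff=%g)", len(kept), m, fraction, cutoff)
    return kept


def build_weighted_network(edges: Iterable[EdgeRecord]) -> nx.Graph:
    """Build the undirected analysis graph with distance weights 1/score.

    Nodes are the union of edge endpoints; each edge carries both the
    original ``score`` and the derived ``weight`` attribute.  Disconnected
    graphs are allowed — unreachable targets simply contribute nothing to
    any centrality score downstream.
    """
    g = nx.Graph()
    for e in edges:
        if not (math.isfinite(e.score) and e.score > 0):
            raise ValidationError(f"edge ({e.gene_a}, {e.gene_b}): score must be > 0, got {e.score}")
        g.add_edge(e.gene_a, e.gene_b, score=e.score, weight=1.0 / e.score)
    return g


def network_edge_records(network: nx.Graph) -> list[EdgeRecord]:
    """Recover the edge list (with scores) from a built network."""
    return [
        EdgeRecord(*sorted((a, b)), score=data["score"])
        for a, b, data in network.edges(data=True)
    ]


def write_edge_list(
    edges_or_network: Union[Sequence[EdgeRecord], nx.Graph],
    destination: Union[PathLike, TextIO],
    header: bool = True,
) -> None:
    """Write edges as TSV: geneA, geneB, score, weight.

    Scores are written with ``repr`` round-trip precision so that reading the
    file back rebuilds an identical network.  Rows are sorted by descending
    score then symbol pair, for deterministic output.
    """
    if isinstance(edges_or_network, nx.Graph):
        edges = network_edge_records(edges_or_network)
    else:
        edges = list(edges_or_network)
    edges = sorted(edges, key=lambda e: (-e.score, e.key()))
    out, owned = (open(destination, "w", encoding="utf-8"), True) if isinstance(
        destination, (str, Path)
    ) else (destination, False)
    try:
        if header:
            out.write("gene_a\tgene_b\tscore\tweight\n")
        for e in edges:
            out.write(f"{e.gene_a}\t{e.gene_b}\t{e.score!r}\t{1.0 / e.score!r}\n")
    finally:
        if owned:
            out.close()
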