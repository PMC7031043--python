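"""Hypergeometric over-representation of a gene list against pathway sets.

Given a query list (typically the mediator genes), a GMT pathway
collection, and a gene universe (the analysis network's node set by
default), each pathway is scored with the upper hypergeometric tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the pathway genes inside the universe,
n the query genes inside the universe, and k their overlap.  The test is
one-sided (over-representation only) and p-values are BH-adjusted across
all pathways with K >= 1 in the universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, ParameterError
from .significance import bh_adjust

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets, symbols normalized to uppercase."""

    sets: dict[str, frozenset[str]]
    source: str = "<memory>"

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(source: Union[str, Path, TextIO]) -> GeneSetCollection:
    """Parse a GMT file: name, description, then member genes, tab-separated.

    Duplicate genes within a line are deduplicated; duplicate set names or
    lines with fewer than 3 fields raise :class:`FormatError` with the line
    number.
    """
    if isinstance(source, (str, Path)):
        stream, owned, name = open(source, "r", encoding="utf-8"), True, str(source)
    else:
        stream, owned, name = source, False, getattr(source, "name", "<stream>")
    sets: dict[str, frozenset[str]] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT line needs >=3 fields, got {len(fields)}")
            set_name = fields[0].strip()
            if set_name in sets:
                raise FormatError(f"line {lineno}: duplicate gene-set name {set_name!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"line {lineno}: gene set {set_name!r} is empty")
            sets[set_name] = genes
    finally:
        if owned:
            stream.close()
    return GeneSetCollection(sets=sets, source=name)


def hypergeometric_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of the query against every pathway.

    Query genes outside the universe are dropped (logged).  Pathways with no
    member inside the universe are excluded from the BH family.  Returns a
    DataFrame sorted by ascending p then pathway name with columns
    pathway, N, K, n, k, p_value, fdr, overlap_genes.
    """
    universe_set = {g.strip().upper() for g in universe}
    if not universe_set:
        raise ParameterError("universe is empty")
    query_set = {g.strip().upper() for g in query}
    if not query_set:
        raise ParameterError("query gene list is empty")
    dropped = query_set - universe_set
    if dropped:
        log.info("dropped %d query gene(s) outside the universe", len(dropped))
    query_set &= universe_set
    if not query_set:
        raise ParameterError("no query gene lies inside the universe")

    n_big = len(universe_set)
    n_query = len(query_set)
    rows = []
    for name in sorted(collection.sets):
        pathway_in_universe = collection.sets[name] & universe_set
        big_k = len(pathway_in_universe)
        if big_k == 0:
            continue
        overlap = sorted(query_set & pathway_in_universe)
        k = len(overlap)
        # sf(k-1) = P(X >= k); k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, n_big, big_k, n_query))
        rows.append(
            {
                "pathway": name,
                "N": n_big,
                "K": big_k,
                "n": n_query,
                "k": k,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "pathway"]).reset_index(drop=True)
        table = table[["pathway", "N", "K", "n", "k", "p_value", "fdr", "overlap_genes"]]
    return table


def write_enrichment(table: pd.DataFrame, destination: Union[str, Path]) -> None:
    table.to_csv(destination, sep="\t", index=False)
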