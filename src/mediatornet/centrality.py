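"""Source-to-set restricted betweenness centrality on a weighted gene network.

For a fixed source gene ``s`` (here the 5-HT2A receptor gene) and a target
gene set ``T``, the statistic for gene ``g`` is

    BC(g) = sum over t in T of  sigma(s, t | g) / sigma(s, t)

where sigma(s, t) counts minimum-total-weight paths between s and t and
sigma(s, t | g) counts those on which g lies as an interior node.  Each
term is a fraction in [0, 1]; BC(g) is the expected number of target-bound
shortest paths that route through g.  Targets unreachable from the source
contribute zero (sigma = 0 terms are skipped), and the endpoints of a pair
contribute zero to that pair's term.

Implementation notes
--------------------
Distances come from Dijkstra (networkx); the shortest-path DAG and the path
multiplicities are then rebuilt with a *relative* tie tolerance, because
reciprocal-score weights are floats and exact equality would under-count
tied routes.  A per-target contribution matrix C[g, t] = sigma(s,t|g) /
sigma(s,t) is exposed so that permutation testing can re-score thousands of
random target sets as simple column sums without re-running any graph
algorithm.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import MediatorNetError, SizeError, ValidationError

log = logging.getLogger(__name__)

#: relative tolerance used to decide that two path lengths tie
TIE_TOL = 1e-9

#: sigma counts above this lose integer exactness in double precision
_COUNT_GUARD = 2.0**53


@dataclass(frozen=True)
class CentralityQuery:
    """A validated (source, target set) pair for one network.

    ``targets`` holds only the target symbols present in the network;
    symbols that had to be dropped are kept in ``missing_targets``.
    """

    source: str
    targets: frozenset[str]
    missing_targets: frozenset[str] = field(default_factory=frozenset)


def make_query(network: nx.Graph, source: str, targets: Iterable[str]) -> CentralityQuery:
    """Validate a source symbol and a target list against a network.

    Target symbols absent from the network are dropped (and logged); the
    source is never allowed inside the target set.
    """
    if source not in network:
        raise ValidationError(f"source gene {source!r} is not in the network")
    requested = {t for t in targets}
    requested.discard(source)
    present = frozenset(t for t in requested if t in network)
    missing = frozenset(requested - present)
    if missing:
        log.info("dropped %d target symbol(s) absent from the network: %s",
                 len(missing), ", ".join(sorted(missing)[:10]))
    if not present:
        raise ValidationError("no target gene is present in the network")
    return CentralityQuery(source=source, targets=present, missing_targets=missing)


@dataclass
class PathCounts:
    """Single-source shortest-path structure with path multiplicities.

    Attributes
    ----------
    source : str
    dist : dict
        Shortest-path distance from the source (absent keys = unreachable,
        read through :meth:`distance` as +inf).
    sigma : dict
        Number of minimum-weight paths from the source to each reachable
        node (float-valued counts; a warning is logged past 2**53).
    predecessors : dict
        Shortest-path DAG: for each reachable node, the neighbors u such
        that dist(u) + w(u, v) == dist(v) within the tie tolerance.
    order : list
        Reachable nodes sorted by increasing distance (source first).
    """

    source: str
    dist: dict[str, float]
    sigma: dict[str, float]
    predecessors: dict[str, list[str]]
    order: list[str]

    def distance(self, node: str) -> float:
        return self.dist.get(node, math.inf)

    def sigma_total(self, target: str) -> float:
        """sigma(s, t): 0 if t is unreachable or t == s."""
        if target == self.source:
            return 0.0
        return self.sigma.get(target, 0.0)

    def _dag_path_counts_to(self, target: str) -> dict[str, float]:
        """Number of DAG paths from each node to ``target`` (tau)."""
        # propagate backward through the DAG in descending distance order
        # so every successor is finished before its predecessors
        tau: dict[str, float] = {target: 1.0}
        for v in reversed(self.order):
            tv = tau.get(v)
            if tv is None:
                continue
            for u in self.predecessors[v]:
                tau[u] = tau.get(u, 0.0) + tv
        return tau

    def sigma_through(self, gene: str, target: str) -> float:
        """sigma(s, t | g): shortest s-t paths with g as an interior node."""
        st = self.sigma_total(target)
        if st == 0.0 or gene in (self.source, target) or gene not in self.sigma:
            return 0.0
        tau = self._dag_path_counts_to(target)
        return self.sigma[gene] * tau.get(gene, 0.0)


def shortest_path_counts(network: nx.Graph, source: str, tol: float = TIE_TOL) -> PathCounts:
    """Weighted single-source shortest paths with path multiplicity.

    An edge (u, v) lies on a shortest path into v iff
    ``|dist(u) + w(u, v) - dist(v)| <= tol * max(1, dist(v))``; sigma
    accumulates over all tied predecessors.
    """
    if source not in network:
        raise ValidationError(f"source gene {source!r} is not in the network")
    dist = nx.single_source_dijkstra_path_length(network, source, weight="weight")
    order = sorted(dist, key=lambda n: (dist[n], n))
    predecessors: dict[str, list[str]] = {}
    sigma: dict[str, float] = {}
    warned = False
    for v in order:
        if v == source:
            predecessors[v] = []
            sigma[v] = 1.0
            continue
        dv = dist[v]
        tolerance = tol * max(1.0, dv)
        preds = [
            u
            for u in network[v]
            if u in dist and abs(dist[u] + network[v][u]["weight"] - dv) <= tolerance
        ]
        predecessors[v] = preds
        sv = sum(sigma[u] for u in preds)
        sigma[v] = sv
        if sv > _COUNT_GUARD and not warned:
            log.warning("shortest-path counts exceed 2^53; multiplicities lose exactness")
            warned = True
    return PathCounts(source=source, dist=dist, sigma=sigma, predecessors=predecessors, order=order)


def contribution_matrix(
    counts: PathCounts, nodes: Sequence[str]
) -> tuple[np.ndarray, dict[str, int]]:
    """Per-target contribution matrix C[g, t] = sigma(s,t|g) / sigma(s,t).

    Rows and columns are indexed by ``nodes`` (any ordering covering the
    network).  Columns for unreachable nodes or the source are zero; the
    endpoint convention zeroes the source row, the diagonal, and each
    target's own column entry.  Summing the columns of any target set gives
    the restricted betweenness of every gene at once — this is what makes
    large permutation runs cheap.
    """
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    # tau[u, t] = number of shortest-path-DAG paths from u to t, computed
    # for all t simultaneously by one backward sweep over the DAG
    tau = np.zeros((n, n))
    reachable = [v for v in counts.order if v != counts.source]
    for v in reachable:
        tau[index[v], index[v]] = 1.0
    for v in reversed(counts.order):
        iv = index[v]
        row = tau[iv]
        if not row.any():
            continue
        for u in counts.predecessors[v]:
            if u == counts.source:
                continue
            tau[index[u]] += row
    # tau currently counts paths u -> t including u == t; convert to
    # interior-passage fractions
    c = np.zeros((n, n))
    sigma_vec = np.zeros(n)
    for v, sv in counts.sigma.items():
        sigma_vec[index[v]] = sv
    for t in reachable:
        it = index[t]
        st = counts.sigma[t]
        if st <= 0:
            continue
        col = sigma_vec * tau[:, it] / st
        col[it] = 0.0
        col[index[counts.source]] = 0.0
        c[:, it] = col
    return c, index


def subset_betweenness(network: nx.Graph, query: CentralityQuery) -> dict[str, float]:
    """BC(g) for every network gene, restricted to source -> target-set paths.

    Returns a dict over *all* network nodes (zeros included); genes in the
    target set are scored like any other gene, as interior nodes of the
    other targets' paths.
    """
    counts = shortest_path_counts(network, query.source)
    nodes = sorted(network.nodes)
    c, index = contribution_matrix(counts, nodes)
    cols = [index[t] for t in query.targets]
    bc = c[:, cols].sum(axis=1)
    return {g: float(bc[index[g]]) for g in nodes}


def brute_force_betweenness(
    network: nx.Graph, query: CentralityQuery, max_nodes: int = 14
) -> dict[str, float]:
    """Oracle: restricted betweenness by exhaustive simple-path enumeration.

    Enumerates every simple path from the source to each target, keeps the
    paths of minimum total weight (relative tie tolerance), and counts
    interior passages directly.  Only usable on small graphs.
    """
    if network.number_of_nodes() > max_nodes:
        raise SizeError(f"brute-force oracle limited to {max_nodes} nodes")
    bc = {g: 0.0 for g in network.nodes}
    for t in query.targets:
        if t not in network:
            continue
        best = math.inf
        shortest: list[list[str]] = []
        try:
            paths = nx.all_simple_paths(network, query.source, t)
        except nx.NodeNotFound:
            continue
        for path in paths:
            length = sum(
                network[u][v]["weight"] for u, v in itertools.pairwise(path)
            )
            if not shortest or length < best - TIE_TOL * max(1.0, best):
                best = length
                shortest = [path]
            elif abs(length - best) <= TIE_TOL * max(1.0, best):
                shortest.append(path)
        if not shortest:
            continue
        st = len(shortest)
        for path in shortest:
            for g in path[1:-1]:
                bc[g] += 1.0 / st
    return bc


def write_centrality(
    bc: Mapping[str, float], query: CentralityQuery, destination
) -> None:
    """Write per-gene scores as TSV (gene, bc, in_target_set), bc descending."""
    from pathlib import Path

    rows = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    out, owned = (open(destination, "w", encoding="utf-8"), True) if isinstance(
        destination, (str, Path)
    ) else (destination, False)
    try:
        out.write("gene\tbc\tin_target_set\n")
        for g, score in rows:
            out.write(f"{g}\t{score!r}\t{str(g in query.targets).lower()}\n")
    finally:
        if owned:
            out.close()
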