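"""Permutation significance for restricted betweenness, BH FDR, mediator calls.

The null model: target sets of the same size as the real one, drawn
uniformly without replacement from a candidate universe (all network genes
except the source, by default).  For each gene g the p-value is the
fraction of permuted sets whose restricted betweenness for g is at least
the observed one.  Because betweenness is non-negative, any gene with an
observed score of zero gets p = 1 automatically.

Each permuted set is scored for *all* genes in one pass: the shortest-path
structure from the source does not depend on the target set, so a single
contribution matrix is computed once and every permutation reduces to a
column sum.  This makes the procedure exact (no approximation relative to
re-running the centrality per permutation) and fast enough for the
100,000-permutation setting.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import CentralityQuery, contribution_matrix, shortest_path_counts
from .errors import ParameterError, SizeError, ValidationError

log = logging.getLogger(__name__)

#: comparisons BC_perm >= BC_obs use this relative slack so that genuinely
#: equal scores reached by different summation orders still count as ties
_GE_TOL = 1e-12


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation null.

    ``n_permutations`` defaults to the published setting of 100,000 —
    synthetic-scale runs typically lower it.  ``candidate_universe`` of
    ``None`` means all network genes except the source.  ``add_one_smoothing``
    replaces k/n with (k+1)/(n+1); ``degree_matched`` draws each permuted
    target from the degree-decile bin of a real target instead of uniformly.
    """

    n_permutations: int = 100_000
    seed: int = 0
    candidate_universe: Optional[frozenset[str]] = None
    add_one_smoothing: bool = False
    degree_matched: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")


def _resolve_universe(
    network: nx.Graph, query: CentralityQuery, config: PermutationConfig
) -> list[str]:
    if config.candidate_universe is None:
        universe = set(network.nodes)
    else:
        universe = {g for g in config.candidate_universe if g in network}
    universe.discard(query.source)
    if len(universe) < len(query.targets):
        raise ParameterError(
            f"candidate universe ({len(universe)}) smaller than target set ({len(query.targets)})"
        )
    return sorted(universe)


def _scoring_matrix(network: nx.Graph, query: CentralityQuery):
    nodes = sorted(network.nodes)
    counts = shortest_path_counts(network, query.source)
    c, index = contribution_matrix(counts, nodes)
    return nodes, c, index


def _degree_bins(network: nx.Graph, universe: Sequence[str], n_bins: int = 10):
    """Assign universe genes to degree-decile bins for matched sampling."""
    degrees = np.array([network.degree(g) for g in universe], dtype=float)
    quantiles = np.quantile(degrees, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_of = np.searchsorted(quantiles, degrees, side="right")
    members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)
    }
    return bin_of, members


def permutation_pvalues(
    network: nx.Graph,
    query: CentralityQuery,
    config: PermutationConfig,
    observed: Optional[Mapping[str, float]] = None,
) -> pd.Series:
    """Monte-Carlo permutation p-values for every network gene.

    p(g) = #{r : BC_r(g) >= BC_obs(g)} / n_permutations, a plain fraction
    that may be 0 (use ``add_one_smoothing`` for (k+1)/(n+1)).  Fully
    reproducible: the same (seed, n_permutations) yields the same vector.

    ``observed`` may carry precomputed observed scores; when omitted they
    are recomputed here with identical arithmetic, which is the safest
    choice for tie handling.
    """
    nodes, c, index = _scoring_matrix(network, query)
    universe = _resolve_universe(network, query, config)
    uni_idx = np.array([index[g] for g in universe])
    k = len(query.targets)

    target_cols = np.array(sorted(index[t] for t in query.targets))
    if observed is None:
        obs = c[:, target_cols].sum(axis=1)
    else:
        obs = np.array([observed[g] for g in nodes])

    rng = np.random.default_rng(config.seed)
    threshold = obs - _GE_TOL * np.maximum(1.0, obs)
    exceed = np.zeros(len(nodes), dtype=np.int64)

    if config.degree_matched:
        real_targets = sorted(query.targets)
        pos_in_universe = {g: i for i, g in enumerate(universe)}
        bin_of, members = _degree_bins(network, universe)
        target_bins = [bin_of[pos_in_universe[t]] for t in real_targets if t in pos_in_universe]
        for _ in range(config.n_permutations):
            chosen: set[int] = set()
            for b in target_bins:
                pool = members[b]
                g = int(pool[rng.integers(len(pool))])
                # resample within the bin on collision; fall back to uniform
                for _retry in range(20):
                    if g not in chosen:
                        break
                    g = int(pool[rng.integers(len(pool))])
                while g in chosen:
                    g = int(rng.integers(len(universe)))
                chosen.add(g)
            cols = uni_idx[np.fromiter(chosen, dtype=int)]
            exceed += c[:, cols].sum(axis=1) >= threshold
    else:
        for _ in range(config.n_permutations):
            cols = uni_idx[rng.choice(len(universe), size=k, replace=False)]
            exceed += c[:, cols].sum(axis=1) >= threshold

    if config.add_one_smoothing:
        p = (exceed + 1) / (config.n_permutations + 1)
    else:
        p = exceed / config.n_permutations
    return pd.Series(p, index=nodes, name="p_value")


def exhaustive_pvalues(
    network: nx.Graph,
    query: CentralityQuery,
    candidate_universe: Optional[Iterable[str]] = None,
    max_combinations: int = 10_000,
) -> pd.Series:
    """Oracle: exact permutation p-values by enumerating every target set.

    Enumerates all size-|T| subsets of the candidate universe; usable only
    when C(|U|, |T|) <= ``max_combinations``.
    """
    cfg = PermutationConfig(
        n_permutations=1,
        candidate_universe=frozenset(candidate_universe) if candidate_universe is not None else None,
    )
    nodes, c, index = _scoring_matrix(network, query)
    universe = _resolve_universe(network, query, cfg)
    k = len(query.targets)
    total = math.comb(len(universe), k)
    if total > max_combinations:
        raise SizeError(f"C({len(universe)}, {k}) = {total} exceeds guard {max_combinations}")

    target_cols = np.array(sorted(index[t] for t in query.targets))
    obs = c[:, target_cols].sum(axis=1)
    threshold = obs - _GE_TOL * np.maximum(1.0, obs)
    exceed = np.zeros(len(nodes), dtype=np.int64)
    uni_cols = np.array([index[g] for g in universe])
    for combo in itertools.combinations(range(len(universe)), k):
        cols = uni_cols[list(combo)]
        exceed += c[:, cols].sum(axis=1) >= threshold
    return pd.Series(exceed / total, index=nodes, name="p_value")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def centrality_table(
    bc: Mapping[str, float],
    p_values: pd.Series,
    query: CentralityQuery,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Assemble the per-gene results table with FDR and mediator calls.

    BH is applied over every network gene with a computed p-value
    (including zero-centrality genes, whose p is 1); a gene is flagged as a
    mediator when its FDR is at or below the threshold — 0.1 by default —
    and it is not the source itself.
    """
    genes = list(p_values.index)
    table = pd.DataFrame(
        {
            "gene": genes,
            "bc": [bc[g] for g in genes],
            "p_value": p_values.to_numpy(),
        }
    )
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["mediator"] = (table["fdr"] <= fdr_threshold) & (table["gene"] != query.source)
    table["in_target_set"] = table["gene"].isin(query.targets)
    table = table.sort_values(["fdr", "bc", "gene"], ascending=[True, False, True]).reset_index(
        drop=True
    )
    table.attrs["source"] = query.source
    return table


def select_mediators(table: pd.DataFrame, fdr_threshold: float = 0.1) -> list[str]:
    """Genes with FDR <= threshold, sorted by ascending FDR then descending BC.

    The source gene is never returned even at a permissive threshold.
    """
    if "fdr" not in table.columns:
        raise ValidationError("table lacks an 'fdr' column")
    source = table.attrs.get("source")
    hits = table[(table["fdr"] <= fdr_threshold) & (table["gene"] != source)]
    hits = hits.sort_values(["fdr", "bc", "gene"], ascending=[True, False, True])
    return list(hits["gene"])
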