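"""Synthetic study generator: networks with planted mediators, DE tables
with designed overlaps, pathway collections, and behavioral cohorts.

The network generator emulates a tissue-specific functional network that
has already been reduced to its strongest edges: a sparse background graph
whose scores sit well below a planted tier.  A source gene (the receptor),
a small mediator layer, and a target layer are wired source->mediator and
mediator->target at a high planted score (0.95), while background scores
are bounded at 0.9 and direct source-target edges are excluded.  Under
reciprocal weighting the planted two-hop route (2/0.95 ~ 2.105) is then
strictly shorter than any background alternative (>= 2/0.9 ~ 2.22), so
every planted target is reached through its mediator — the ground truth
that recovery tests score against.

Default scale (400 genes, 5 mediators, 25 targets, average background
degree ~10) keeps a full pipeline run with thousands of permutations in
the seconds range while leaving the permutation null non-degenerate:
mediators participate in the background graph like any other gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .network_model import EdgeRecord
from .significance import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_SOURCE = "HTR2A"


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of the planted-mediator network generator."""

    n_genes: int = 400
    n_mediators: int = 5
    n_targets: int = 25
    n_background_edges: int = 2000
    topology: str = "uniform-random"  # or "preferential-attachment"
    score_low: float = 0.2
    score_high: float = 0.9
    planted_score: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mediators + self.n_targets + 1 > self.n_genes:
            raise ParameterError("n_mediators + n_targets + 1 must not exceed n_genes")
        if not 0 < self.planted_score <= 1:
            raise ParameterError("planted_score must lie in (0, 1]")
        if not 0 < self.score_low < self.score_high:
            raise ParameterError("need 0 < score_low < score_high")
        if self.score_high >= self.planted_score:
            raise ParameterError("background scores must stay below the planted score")
        if self.topology not in ("uniform-random", "preferential-attachment"):
            raise ParameterError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels of the generated network."""

    source: str
    mediators: tuple[str, ...]
    targets: tuple[str, ...]
    target_mediator: dict[str, str] = field(default_factory=dict)

    def is_mediator(self, gene: str) -> bool:
        return gene in self.mediators


def _gene_names(spec: SyntheticNetworkSpec) -> tuple[str, list[str], list[str], list[str]]:
    mediators = [f"MED{i + 1:02d}" for i in range(spec.n_mediators)]
    targets = [f"TGT{i + 1:02d}" for i in range(spec.n_targets)]
    n_background = spec.n_genes - 1 - spec.n_mediators - spec.n_targets
    background = [f"G{i + 1:04d}" for i in range(n_background)]
    return DEFAULT_SOURCE, mediators, targets, background


def generate_network(spec: SyntheticNetworkSpec) -> tuple[list[EdgeRecord], PlantedTruth]:
    """Draw a background graph and plant the source->mediator->target layer.

    Background edges avoid duplicating planted pairs and never connect the
    source directly to a target, so the planted two-hop route stays the
    unique shortest path to each target.  Mediators take part in no
    background edges at all: their centrality is specific to the planted
    target layer, exactly the excess the permutation test is meant to
    detect.  Targets stay attached to the background, but only through
    weak (bottom-of-range) scores — they are peripheral genes whose strong
    links run through the planted pathway — so reaching a target cheaply
    through its mediator never doubles as a shortcut into the rest of the
    graph.  Deterministic given the seed.
    """
    source, mediators, targets, background = _gene_names(spec)
    all_genes = [source] + background  # mediators/targets wired separately
    rng = np.random.default_rng(spec.seed)

    planted_pairs: set[tuple[str, str]] = set()
    records: list[EdgeRecord] = []
    target_mediator: dict[str, str] = {}
    for m in mediators:
        pair = tuple(sorted((source, m)))
        planted_pairs.add(pair)
        records.append(EdgeRecord(pair[0], pair[1], spec.planted_score))
    for i, t in enumerate(targets):
        if not mediators:
            break
        m = mediators[i % len(mediators)]
        target_mediator[t] = m
        pair = tuple(sorted((m, t)))
        planted_pairs.add(pair)
        records.append(EdgeRecord(pair[0], pair[1], spec.planted_score))

    n = len(all_genes)
    max_pairs = n * (n - 1) // 2
    if spec.n_background_edges > max_pairs - len(planted_pairs):
        raise ParameterError("n_background_edges exceeds the number of available gene pairs")

    forbidden = set(planted_pairs)
    for t in targets:
        forbidden.add(tuple(sorted((source, t))))

    chosen: set[tuple[str, str]] = set()
    if spec.topology == "preferential-attachment":
        # grow by repeated degree-biased endpoint selection
        degree = {g: 1.0 for g in all_genes}
        genes = np.array(all_genes)
        attempts = 0
        while len(chosen) < spec.n_background_edges:
            attempts += 1
            if attempts > 50 * spec.n_background_edges:
                raise ParameterError("background generation stalled; density infeasible")
            weights = np.array([degree[g] for g in all_genes])
            a, b = rng.choice(n, size=2, replace=False, p=weights / weights.sum())
            pair = tuple(sorted((genes[a], genes[b])))
            if pair in forbidden or pair in chosen:
                continue
            chosen.add(pair)
            degree[pair[0]] += 1
            degree[pair[1]] += 1
    else:
        attempts = 0
        while len(chosen) < spec.n_background_edges:
            attempts += 1
            if attempts > 50 * spec.n_background_edges:
                raise ParameterError("background generation stalled; density infeasible")
            a, b = rng.integers(0, n, size=2)
            if a == b:
                continue
            pair = tuple(sorted((all_genes[a], all_genes[b])))
            if pair in forbidden or pair in chosen:
                continue
            chosen.add(pair)

    span = spec.score_high - spec.score_low
    for pair in sorted(chosen):
        score = spec.score_low + span * rng.beta(2.0, 2.0)
        records.append(EdgeRecord(pair[0], pair[1], float(score)))

    # weak target-background attachment: scores from the bottom third of
    # the background range, so the planted gateway is never a shortcut
    # into the target's neighborhood
    if background:
        for t in targets:
            neighbors = rng.choice(len(background), size=min(2, len(background)), replace=False)
            for j in neighbors:
                pair = tuple(sorted((t, background[j])))
                if pair in chosen or pair in forbidden:
                    continue
                score = spec.score_low + (span / 3.0) * rng.random()
                records.append(EdgeRecord(pair[0], pair[1], float(score)))
                chosen.add(pair)

    truth = PlantedTruth(
        source=source,
        mediators=tuple(mediators),
        targets=tuple(targets),
        target_mediator=target_mediator,
    )
    return records, truth


DEFAULT_OVERLAP_DESIGN = {
    "a_only": 100,
    "b_only": 40,
    "c_only": 60,
    "ab": 30,
    "ac": 10,
    "bc": 10,
    "abc": 20,
}

DEFAULT_CONTRASTS = ("Sh_vs_Gh", "Sh_vs_ShFlx", "ShFlxAnx_vs_Gh")


def generate_de_tables(
    n_genes: int = 2000,
    overlap_design: Optional[dict[str, int]] = None,
    alpha: float = 0.05,
    seed: int = 0,
    contrasts: Sequence[str] = DEFAULT_CONTRASTS,
    direction_consistent_fraction: float = 0.8,
) -> tuple[dict[str, pd.DataFrame], dict[str, set[str]]]:
    """Three differential-expression tables with designed significant-set overlaps.

    ``overlap_design`` gives the sizes of the seven Venn regions of the
    three significant sets A, B, C (keys as in
    :func:`mediatornet.cohort_sets.three_way_overlap`); the default design
    yields |A ∩ B| = 50, a convenient treatment-normalized intersection.
    Designed genes receive p-values far below ``alpha``; null genes receive
    p-values that keep BH from ever promoting them past ``alpha``, so
    thresholding adj_p at ``alpha`` recovers each designed set exactly.
    When the design is empty (pure null), p-values are uniform on (0, 1).

    Fold-change signs are drawn so that ``direction_consistent_fraction``
    of the A ∩ B genes move the same way in both contrasts and the rest
    move oppositely, exercising the direction-consistency filter.

    Returns (tables keyed by contrast label, designed sets {"A","B","C"}).
    """
    if len(contrasts) != 3:
        raise ParameterError("exactly three contrast labels are required")
    design = dict(DEFAULT_OVERLAP_DESIGN if overlap_design is None else overlap_design)
    unknown = set(design) - set(DEFAULT_OVERLAP_DESIGN)
    if unknown:
        raise ParameterError(f"unknown Venn region key(s): {sorted(unknown)}")
    for key in DEFAULT_OVERLAP_DESIGN:
        design.setdefault(key, 0)
        if design[key] < 0:
            raise ParameterError(f"region size {key} must be >= 0")
    n_designed = sum(design.values())
    if n_designed > n_genes:
        raise ParameterError("overlap design larger than the gene pool")
    if not 0 <= direction_consistent_fraction <= 1:
        raise ParameterError("direction_consistent_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    rng.shuffle(genes)

    pos = 0
    region_genes: dict[str, list[str]] = {}
    for key in sorted(DEFAULT_OVERLAP_DESIGN):
        region_genes[key] = list(genes[pos : pos + design[key]])
        pos += design[key]

    set_a = set(region_genes["a_only"]) | set(region_genes["ab"]) | set(region_genes["ac"]) | set(region_genes["abc"])
    set_b = set(region_genes["b_only"]) | set(region_genes["ab"]) | set(region_genes["bc"]) | set(region_genes["abc"])
    set_c = set(region_genes["c_only"]) | set(region_genes["ac"]) | set(region_genes["bc"]) | set(region_genes["abc"])
    designed = {"A": set_a, "B": set_b, "C": set_c}

    # one shared sign per gene for contrast A; contrast B flips the sign for
    # the designated direction-inconsistent share of the A∩B genes
    base_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in genes}
    ab_genes = sorted(set_a & set_b)
    n_consistent = int(round(direction_consistent_fraction * len(ab_genes)))
    flipped = set(ab_genes[n_consistent:])

    tables: dict[str, pd.DataFrame] = {}
    for label, sig_set in zip(contrasts, (set_a, set_b, set_c)):
        gene_order = sorted(genes)
        is_sig = np.array([g in sig_set for g in gene_order])
        p = np.empty(n_genes)
        n_sig = int(is_sig.sum())
        p[is_sig] = rng.uniform(1e-10, 1e-7, size=n_sig)
        if n_designed == 0:
            p[~is_sig] = rng.uniform(0.0, 1.0, size=n_genes - n_sig)
        else:
            # nulls bounded away from alpha so BH cannot promote them
            p[~is_sig] = alpha + (1.0 - alpha) * rng.uniform(0.0, 1.0, size=n_genes - n_sig)
        lfc = rng.normal(0.0, 0.2, size=n_genes)
        for i, g in enumerate(gene_order):
            if is_sig[i]:
                sign = base_sign[g]
                if label == contrasts[1] and g in flipped:
                    sign = -sign
                lfc[i] = sign * rng.uniform(0.8, 2.5)
        table = pd.DataFrame(
            {
                "gene": gene_order,
                "log2fc": lfc,
                "p": p,
                "adj_p": bh_adjust(p),
            }
        )
        table.attrs["contrast"] = label
        tables[label] = table
    return tables, designed


def generate_behavior(
    group_sizes: Optional[dict[str, int]] = None,
    shelter_baseline: float = 150.0,
    shelter_sd: float = 30.0,
    stress_shift: float = 250.0,
    normalized_margin: float = 90.0,
    anxious_fraction: float = 13 / 24,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Behavioral cohort with a planted anxious subgroup among treated animals.

    Group-housed controls (Gh) draw shelter times around the baseline;
    isolated animals (Sh) are shifted up by ``stress_shift`` seconds; of the
    fluoxetine-treated isolated animals (Sh+Flx), exactly
    ``round(anxious_fraction * n)`` stay at the stressed level and receive
    an open-field center/periphery ratio below 0.25, while the rest drop to
    ``normalized_margin`` seconds below baseline with unremarkable ratios.
    Default group sizes follow the open-field cohort (11 Gh, 12 Sh, 24
    treated of which 13 anxious).

    The margin exists because the shelter-anxiety cutoff (control mean plus
    twice the control SEM) sits well inside the control distribution
    itself: treated animals drawn from the control distribution would cross
    it at the null upper-tail rate, so planted labels are only recoverable
    when normalized animals sit a few control standard deviations below
    the cutoff.  The default margin is three times ``shelter_sd``, with the
    normalized animals' own spread tightened by the same factor.

    Returns (behavior table, planted anxious labels by animal id).
    """
    sizes = {"Gh": 11, "Sh": 12, "Sh+Flx": 24} if group_sizes is None else dict(group_sizes)
    for group, size in sizes.items():
        if size < 2:
            raise ParameterError(f"group {group!r} needs >= 2 animals")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, bool] = {}
    for group in ("Gh", "Sh", "Sh+Flx"):
        n = sizes.get(group, 0)
        if group == "Sh+Flx":
            n_anxious = int(round(anxious_fraction * n))
            anxious_flags = [True] * n_anxious + [False] * (n - n_anxious)
        elif group == "Sh":
            anxious_flags = [True] * n
        else:
            anxious_flags = [False] * n
        for i, anxious in enumerate(anxious_flags):
            animal = f"{group.replace('+', '')}_{i + 1:02d}"
            if anxious:
                mean, sd = shelter_baseline + stress_shift, shelter_sd
            elif group == "Sh+Flx":
                # normalized animals: margin below the SEM-based cutoff
                mean, sd = shelter_baseline - normalized_margin, shelter_sd / 3.0
            else:
                mean, sd = shelter_baseline, shelter_sd
            shelter = float(np.clip(rng.normal(mean, sd), 0.0, 900.0))
            if group == "Sh+Flx" and anxious:
                ratio = float(rng.uniform(0.05, 0.20))
            else:
                ratio = float(rng.uniform(0.35, 0.80))
            rows.append(
                {
                    "animal": animal,
                    "group": group,
                    "shelter_time_s": shelter,
                    "center_periphery_ratio": ratio,
                }
            )
            truth[animal] = bool(anxious)
    return pd.DataFrame(rows), truth


def generate_pathways(
    truth: PlantedTruth,
    background_genes: Sequence[str],
    n_decoy_sets: int = 20,
    decoy_size: int = 15,
    n_decoys_in_planted: int = 5,
    seed: int = 0,
) -> dict[str, list[str]]:
    """A GMT-style collection with one planted pathway (mediators + decoys)
    and random decoy pathways drawn from the background genes."""
    rng = np.random.default_rng(seed)
    pool = [g for g in background_genes if g not in truth.mediators and g != truth.source]
    if len(pool) < max(decoy_size, n_decoys_in_planted):
        raise ParameterError("not enough background genes for the pathway collection")
    sets: dict[str, list[str]] = {}
    planted_extra = list(rng.choice(pool, size=n_decoys_in_planted, replace=False))
    sets["PLANTED_MEDIATOR_PATHWAY"] = sorted(set(truth.mediators) | set(planted_extra))
    for i in range(n_decoy_sets):
        members = rng.choice(pool, size=min(decoy_size, len(pool)), replace=False)
        sets[f"DECOY_PATHWAY_{i + 1:02d}"] = sorted(set(members))
    return sets


def write_gmt(sets: dict[str, Sequence[str]], destination) -> None:
    """Write a pathway collection in GMT format (name, description, genes)."""
    with open(destination, "w", encoding="utf-8") as out:
        for name in sets:
            genes = "\t".join(sets[name])
            out.write(f"{name}\tsynthetic\t{genes}\n")


def write_simulation_bundle(outdir, seed: int = 0, spec: Optional[SyntheticNetworkSpec] = None):
    """Write a complete synthetic study to ``outdir``.

    Files: edges.tsv, truth.tsv, targets.txt, de_<contrast>.tsv,
    pathways.gmt, behavior.csv.  The target list is the planted target
    layer, so a pipeline run on the bundle can be scored against truth.tsv.
    """
    from .network_model import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else SyntheticNetworkSpec(seed=seed)
    edges, truth = generate_network(spec)
    write_edge_list(edges, outdir / "edges.tsv")

    with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\trole\n")
        fh.write(f"{truth.source}\tsource\n")
        for m in truth.mediators:
            fh.write(f"{m}\tmediator\n")
        for t in truth.targets:
            fh.write(f"{t}\ttarget\n")

    (outdir / "targets.txt").write_text("\n".join(truth.targets) + "\n", encoding="utf-8")

    tables, _ = generate_de_tables(seed=seed)
    for label, table in tables.items():
        table.to_csv(outdir / f"de_{label}.tsv", sep="\t", index=False)

    node_pool = sorted({e.gene_a for e in edges} | {e.gene_b for e in edges})
    sets = generate_pathways(truth, node_pool, seed=seed)
    write_gmt(sets, outdir / "pathways.gmt")

    behavior, _ = generate_behavior(seed=seed)
    behavior.to_csv(outdir / "behavior.csv", index=False)
    return truth
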