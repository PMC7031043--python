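"""End-to-end orchestration: network in, mediator table and enrichment out.

Stages: read edge list -> keep top edges -> reciprocal weighting ->
resolve the target set (given directly or built from two DE contrasts) ->
restricted betweenness from the source -> permutation p-values -> BH ->
mediator selection -> pathway enrichment.  Every stage writes its output
so any stage can be re-run in isolation, and a manifest records the
configuration, input checksums and stage counts.  All randomness flows
from the single configured seed, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .errors import ParameterError, ValidationError
from . import cohort_sets, enrichment, network_model, significance
from .centrality import make_query, subset_betweenness, write_centrality

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Full configuration of one mediator-analysis run.

    Defaults mirror the published analysis settings: top 1% of edges,
    100,000 permutations, mediator call at FDR <= 0.1, DE significance at
    adjusted p <= 0.05.  Either ``targets_path`` or both DE table paths
    must be given.
    """

    network_path: str = ""
    source_gene: str = "HTR2A"
    targets_path: Optional[str] = None
    de_stress_path: Optional[str] = None
    de_treatment_path: Optional[str] = None
    gmt_path: Optional[str] = None
    output_dir: str = "mediatornet_out"
    top_edge_fraction: float = 0.01
    n_permutations: int = 100_000
    fdr_threshold: float = 0.1
    de_alpha: float = 0.05
    seed: int = 0
    add_one_smoothing: bool = False
    degree_matched: bool = False
    direction_consistent: bool = False

    def validate(self) -> None:
        if not self.network_path:
            raise ParameterError("network_path is required")
        if not 0 < self.top_edge_fraction <= 1:
            raise ParameterError("top_edge_fraction must lie in (0, 1]")
        if not 0 < self.fdr_threshold <= 1:
            raise ParameterError("fdr_threshold must lie in (0, 1]")
        if self.targets_path is None and not (self.de_stress_path and self.de_treatment_path):
            raise ParameterError("need targets_path, or both de_stress_path and de_treatment_path")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _resolve_targets(config: AnalysisConfig) -> tuple[set[str], dict]:
    """Target set from a gene list file or from the two DE contrasts."""
    info: dict = {}
    if config.targets_path:
        targets = cohort_sets.read_gene_set(config.targets_path)
        info["target_source"] = "gene list"
        return targets, info
    stress = cohort_sets.read_de_table(config.de_stress_path, contrast="stress")
    treatment = cohort_sets.read_de_table(config.de_treatment_path, contrast="treatment")
    sig_stress = cohort_sets.significant_genes(stress, alpha=config.de_alpha)
    sig_treat = cohort_sets.significant_genes(treatment, alpha=config.de_alpha)
    targets = cohort_sets.flx_normalized_set(
        sig_stress,
        sig_treat,
        direction_tables=(stress, treatment),
        require_consistent_direction=config.direction_consistent,
    )
    info.update(
        target_source="DE intersection",
        n_significant_stress=len(sig_stress),
        n_significant_treatment=len(sig_treat),
    )
    return targets, info


def run_mediator_analysis(config: AnalysisConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Writes into ``config.output_dir``: filtered_network.tsv,
    centrality.tsv, results.tsv, mediators.txt, enrichment.tsv (when a
    GMT is configured), and manifest.yaml.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # config echo omits output_dir: the manifest lives inside it, and two
    # runs of the same analysis into different directories are the same run
    config_echo = asdict(config)
    config_echo.pop("output_dir")
    manifest: dict = {
        "tool": {"name": "mediatornet", "version": __version__},
        "config": config_echo,
        "inputs": {},
        "counts": {},
        "assumptions": {
            "edge_ties_at_cutoff": "all retained",
            "duplicate_edges": "maximum score kept",
            "permutation_universe": "all network genes except the source"
            + (" (degree-matched)" if config.degree_matched else " (uniform)"),
            "bh_family": "all network genes",
            "enrichment_universe": "filtered network node set",
        },
    }
    for key in ("network_path", "targets_path", "de_stress_path", "de_treatment_path", "gmt_path"):
        value = getattr(config, key)
        if value:
            manifest["inputs"][key] = {"path": str(value), "sha256": _sha256(value)}

    edges = network_model.read_edge_list(config.network_path)
    manifest["counts"]["edges_in"] = len(edges)
    kept = network_model.filter_top_edges(edges, fraction=config.top_edge_fraction)
    manifest["counts"]["edges_after_filter"] = len(kept)
    network = network_model.build_weighted_network(kept)
    manifest["counts"]["genes_in_network"] = network.number_of_nodes()
    network_model.write_edge_list(network, outdir / "filtered_network.tsv")

    source = config.source_gene.strip().upper()
    if source not in network:
        suggestions = difflib.get_close_matches(source, list(network.nodes), n=3)
        hint = f"; nearest symbols: {', '.join(suggestions)}" if suggestions else ""
        raise ValidationError(f"source gene {source!r} not in the filtered network{hint}")

    targets, target_info = _resolve_targets(config)
    manifest["counts"]["targets_requested"] = len(targets)
    query = make_query(network, source, targets)
    manifest["counts"]["targets_in_network"] = len(query.targets)
    manifest["counts"]["targets_dropped"] = len(query.missing_targets)
    manifest["counts"].update(target_info)

    bc = subset_betweenness(network, query)
    write_centrality(bc, query, outdir / "centrality.tsv")

    perm_config = significance.PermutationConfig(
        n_permutations=config.n_permutations,
        seed=config.seed,
        add_one_smoothing=config.add_one_smoothing,
        degree_matched=config.degree_matched,
    )
    p_values = significance.permutation_pvalues(network, query, perm_config)
    table = significance.centrality_table(bc, p_values, query, fdr_threshold=config.fdr_threshold)
    table.to_csv(outdir / "results.tsv", sep="\t", index=False)
    manifest["counts"]["genes_tested"] = len(table)

    mediators = significance.select_mediators(table, fdr_threshold=config.fdr_threshold)
    cohort_sets.write_gene_set(mediators, outdir / "mediators.txt")
    manifest["counts"]["mediators"] = len(mediators)
    log.info("selected %d mediator(s) at FDR <= %g", len(mediators), config.fdr_threshold)

    if config.gmt_path and mediators:
        collection = enrichment.read_gmt(config.gmt_path)
        enriched = enrichment.hypergeometric_enrichment(
            mediators, collection, universe=network.nodes
        )
        enrichment.write_enrichment(enriched, outdir / "enrichment.tsv")
        manifest["counts"]["pathways_tested"] = len(enriched)
        if len(enriched):
            manifest["counts"]["pathways_fdr_le_threshold"] = int(
                (enriched["fdr"] <= config.fdr_threshold).sum()
            )

    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
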