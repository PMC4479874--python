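"""End-to-end pipeline runner: interfaces -> CCRN -> hubs -> statistics -> regulation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from ccrn import io
from ccrn.ccrn_construction import (
    CCRN,
    Relation,
    build_basic_ccrn,
    build_ccrn,
    identify_specific_proteins,
)
from ccrn.regulation import compare_pair_expression, gene_pcc_from_matrix, isoform_enrichment
from ccrn.statistics import (
    ContingencyTable2x2,
    Direction,
    fisher_exact_one_tailed,
    wilcoxon_rank_sum_one_tailed,
)
from ccrn.structure_interfaces import (
    InterfaceDefinition,
    extract_interface_residues,
    parse_complex,
)
from ccrn.topology import (
    HubCategory,
    classify_hubs,
    mcl_cluster,
    participation_coefficient,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every path is optional except one
    source of interfaces (a precomputed interface TSV or an interaction table
    plus structures and sequences)."""

    out_dir: str
    interface_definition: str = InterfaceDefinition.CBETA_7P5.value
    jaccard_threshold: float = 0.1
    hub_fraction: float = 0.2
    mcl_inflation: float = 2.0
    min_module_size: int = 4
    significance_threshold: float = 0.01
    seed: int = 0
    interfaces_tsv: str | None = None
    interaction_table: str | None = None
    sequences_fasta: str | None = None
    domains_tsv: str | None = None
    reference_domains_tsv: str | None = None
    isoforms_tsv: str | None = None
    essential_tsv: str | None = None
    expression_tsv: str | None = None
    gene_map_tsv: str | None = None

    def __post_init__(self) -> None:
        for name in ("jaccard_threshold", "hub_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.interfaces_tsv is None and self.interaction_table is None:
            raise ValueError("provide interfaces_tsv or interaction_table")


def _load_interface_maps(config: PipelineConfig):
    if config.interfaces_tsv:
        return io.interface_maps_from_sets(io.read_interface_sets(config.interfaces_tsv))
    table = io.read_interaction_table(config.interaction_table)
    sequences = io.read_fasta(config.sequences_fasta)
    definition = InterfaceDefinition(config.interface_definition)
    sets = []
    for row in table.itertuples(index=False):
        cx = parse_complex(
            row.structure_path,
            {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
            sequences,
            interaction_id=row.interaction_id,
        )
        sets.extend(extract_interface_residues(cx, definition))
    return io.interface_maps_from_sets(sets)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; write result tables plus a run manifest.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    tests: list[dict] = []

    maps = _load_interface_maps(config)
    manifest["stages"]["interfaces"] = {
        "n_common_proteins": len(maps),
        "n_interfaces": sum(len(m.partner_interfaces) for m in maps),
    }

    net = build_ccrn(maps, threshold=config.jaccard_threshold)
    net.write_tsv(out / "ccrn_edges.tsv")
    counts = net.edge_counts()
    manifest["stages"]["ccrn"] = {
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        **counts,
    }

    specific = frozenset()
    if config.domains_tsv and config.reference_domains_tsv:
        focal_domains = io.read_domain_table(config.domains_tsv)
        reference_domains = io.read_domain_table(config.reference_domains_tsv)
        species = identify_specific_proteins(
            focal_domains,
            reference_domains,
            focal_nodes=net.graph.nodes,
            reference_nodes=reference_domains.keys(),
        )
        specific = species.specific_proteins
        basic = build_basic_ccrn(net, specific)
        basic.write_tsv(out / "basic_ccrn_edges.tsv")
        manifest["stages"]["basic_ccrn"] = {
            "n_specific_proteins": len(specific),
            "n_nodes": basic.graph.number_of_nodes(),
            "n_edges": basic.graph.number_of_edges(),
        }

    hubs = classify_hubs(net, top_fraction=config.hub_fraction)
    lcc_nodes = max(nx.connected_components(net.graph), key=lambda c: (len(c), sorted(c)[0]))
    lcc = net.graph.subgraph(lcc_nodes).copy()
    partition = mcl_cluster(
        lcc, inflation=config.mcl_inflation, min_module_size=config.min_module_size
    )
    node_to_module = partition.node_to_module()
    hub_rows = []
    for h in hubs:
        p = (
            participation_coefficient(lcc, partition, h.protein)
            if h.protein in node_to_module
            else None
        )
        hub_rows.append(
            {
                "protein": h.protein,
                "degree": h.degree,
                "competitive_fraction": h.competitive_fraction,
                "category": h.category.value,
                "clustering_coefficient": h.clustering_coefficient,
                "participation_coefficient": "" if p is None else p,
            }
        )
    pd.DataFrame(hub_rows).to_csv(out / "hubs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"protein": n, "module_index": i, "retained": int(partition.retained[i])}
            for n, i in sorted(node_to_module.items())
        ]
    ).to_csv(out / "modules.tsv", sep="\t", index=False)
    manifest["stages"]["topology"] = {
        "n_hubs": len(hubs),
        "n_modules": partition.n_modules,
        "hub_categories": {
            c.value: sum(1 for h in hubs if h.category is c) for c in HubCategory
        },
    }

    comp_cc = [h.clustering_coefficient for h in hubs if h.category is HubCategory.COMPETITIVE]
    coop_cc = [h.clustering_coefficient for h in hubs if h.category is HubCategory.COOPERATIVE]
    if len(comp_cc) >= 2 and len(coop_cc) >= 2:
        r = wilcoxon_rank_sum_one_tailed(comp_cc, coop_cc, Direction.X_GREATER)
        tests.append(
            {"test_name": "clustering_competitive_vs_cooperative_hubs",
             "statistic": r.statistic, "p_value": r.p_value,
             "direction": r.direction, "n_x": r.n_x, "n_y": r.n_y}
        )

    if config.essential_tsv:
        essential = io.read_flag_table(config.essential_tsv)
        comp = [h.protein for h in hubs if h.category is HubCategory.COMPETITIVE]
        coop = [h.protein for h in hubs if h.category is HubCategory.COOPERATIVE]
        if comp and coop:
            table = ContingencyTable2x2(
                a=sum(1 for p in coop if p in essential),
                b=sum(1 for p in comp if p in essential),
                c=sum(1 for p in coop if p not in essential),
                d=sum(1 for p in comp if p not in essential),
            )
            tests.append(
                {"test_name": "essential_enrichment_cooperative_hubs",
                 "statistic": float("nan"),
                 "p_value": fisher_exact_one_tailed(table, "greater"),
                 "direction": "cooperative_greater",
                 "n_x": len(coop), "n_y": len(comp)}
            )

    if config.expression_tsv and config.gene_map_tsv:
        expression = io.read_expression_matrix(config.expression_tsv)
        gene_map = io.read_gene_map(config.gene_map_tsv)
        gene_pcc = gene_pcc_from_matrix(expression)
        cmp = compare_pair_expression(net, gene_map, gene_pcc, Direction.Y_GREATER)
        tests.append(
            {"test_name": "pcc_competitive_vs_cooperative_pairs",
             "statistic": cmp.test.statistic, "p_value": cmp.test.p_value,
             "direction": cmp.test.direction,
             "n_x": cmp.n_competitive, "n_y": cmp.n_cooperative}
        )
        manifest["stages"]["expression"] = {
            "median_pcc_competitive": cmp.median_competitive,
            "median_pcc_cooperative": cmp.median_cooperative,
        }

    if config.isoforms_tsv and specific:
        isoforms = io.read_isoform_table(config.isoforms_tsv)
        nonspecific = set(net.graph.nodes) - specific
        enr = isoform_enrichment(specific, nonspecific, isoforms)
        tests.append(
            {"test_name": "isoform_enrichment_specific_proteins",
             "statistic": float("nan"), "p_value": enr.p_value,
             "direction": "specific_greater",
             "n_x": len(specific), "n_y": len(nonspecific)}
        )

    pd.DataFrame(
        tests, columns=["test_name", "statistic", "p_value", "direction", "n_x", "n_y"]
    ).to_csv(out / "test_results.tsv", sep="\t", index=False)
    manifest["stages"]["tests"] = {
        t["test_name"]: {
            "p_value": t["p_value"],
            "significant": bool(t["p_value"] < config.significance_threshold),
        }
        for t in tests
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
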