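"""Seeded generators for every input class of the pipeline, with ground truth.

The generators emulate the structure of a structural interactome study on a
desk scale: toy two-chain complexes with planted interface contacts, partner
interface maps with planted Jaccard overlaps (competitive cliques around
designated hub proteins against a cooperative background), expression
profiles with planted pairwise correlations, and annotation tables with
planted species-specific domains and group-specific isoform rates.

Everything is deterministic given the config seed, and every planted quantity
is returned alongside the data so downstream recovery can be checked exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from ccrn.ccrn_construction import PartnerInterfaceMap, Relation
from ccrn.structure_interfaces import InterfaceDefinition, InterfaceResidueSet

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    The expression correlations (0.1 for competitive, 0.5 for cooperative
    pairs) mirror the observed yeast medians; the multi-isoform rates (0.7
    specific vs 0.5 non-specific) mirror the human isoform table proportions.
    """

    seed: int = 0
    n_common_proteins: int = 30
    partners_per_common: int = 2
    chain_length: int = 120
    planted_jaccard_levels: tuple[float, ...] = (0.3, 0.5)
    n_hub_clusters: int = 4
    cluster_size: int = 8
    rho_competitive: float = 0.1
    rho_cooperative: float = 0.5
    n_samples: int = 100
    n_specific_domains: int = 5
    specific_multi_isoform_rate: float = 0.7
    nonspecific_multi_isoform_rate: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "n_common_proteins", "partners_per_common", "chain_length",
            "n_hub_clusters", "cluster_size", "n_samples", "n_specific_domains",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rho_competitive", "rho_cooperative"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        for name in ("specific_multi_isoform_rate", "nonspecific_multi_isoform_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not 0 <= j <= 1 for j in self.planted_jaccard_levels):
            raise ValueError("planted Jaccard levels must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Toy complex structures
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSet:
    interaction_table: pd.DataFrame
    sequences: dict[str, str]
    true_interfaces: dict[str, dict[str, frozenset[int]]]  # interaction -> protein -> residues
    structure_dir: Path


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _write_pseudo_pdb(
    path: Path,
    chains: Mapping[str, tuple[str, np.ndarray]],
) -> None:
    """Write a C-beta pseudo-atom PDB: one CB per residue (CA for glycine)."""
    structure = gemmi.Structure()
    structure.name = path.stem
    model = gemmi.Model("1")
    for chain_id, (sequence, coords) in chains.items():
        chain = gemmi.Chain(chain_id)
        for i, (letter, xyz) in enumerate(zip(sequence, coords), start=1):
            residue = gemmi.Residue()
            residue.name = AA3[letter]
            residue.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA" if letter == "G" else "CB"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position(*map(float, xyz))
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def generate_toy_complexes(
    config: GeneratorConfig,
    out_dir: str | Path,
    n_complexes: int = 3,
    contacts_per_complex: int = 5,
    contact_distance: float = 6.5,
) -> ToyComplexSet:
    """Two-chain pseudo-atom complexes with planted interface contacts.

    Residues sit on a 10-angstrom grid; the planted contact pairs are placed
    at ``contact_distance`` (strictly inside the 7.5 C-beta cutoff by default,
    or e.g. 3.9 to satisfy the 4.0 heavy-atom cutoff) while every other
    residue pair stays beyond 8.5 angstrom.  Ground-truth interface sets are
    returned for both chains of every complex.
    """
    length = config.chain_length
    if contacts_per_complex > length:
        raise ValueError("more planted contacts than residues per chain")
    if not 0 < contact_distance < 7.5:
        raise ValueError("contact_distance must be inside the planting band (0, 7.5)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    sequences: dict[str, str] = {}
    truth: dict[str, dict[str, frozenset[int]]] = {}
    for idx in range(n_complexes):
        interaction_id = f"CPX{idx:03d}"
        prot_a, prot_b = f"SYNA{idx:03d}", f"SYNB{idx:03d}"
        seq_a = _random_sequence(rng, length)
        seq_b = _random_sequence(rng, length)
        coords_a = np.column_stack(
            [np.zeros(length), 10.0 * np.arange(length), np.zeros(length)]
        )
        coords_b = np.column_stack(
            [np.full(length, 25.0), 10.0 * np.arange(length), np.zeros(length)]
        )
        res_a = rng.choice(length, size=contacts_per_complex, replace=False)
        res_b = rng.choice(length, size=contacts_per_complex, replace=False)
        for ia, ib in zip(res_a, res_b):
            coords_b[ib] = (contact_distance, 10.0 * ia, 0.0)
        path = out_dir / f"{interaction_id}.pdb"
        _write_pseudo_pdb(path, {"A": (seq_a, coords_a), "B": (seq_b, coords_b)})
        sequences[prot_a] = seq_a
        sequences[prot_b] = seq_b
        truth[interaction_id] = {
            prot_a: frozenset(int(i) + 1 for i in res_a),
            prot_b: frozenset(int(i) + 1 for i in res_b),
        }
        rows.append(
            {
                "interaction_id": interaction_id,
                "protein_a": prot_a,
                "protein_b": prot_b,
                "structure_path": str(path),
                "chain_a": "A",
                "chain_b": "B",
            }
        )
    table = pd.DataFrame(rows)
    return ToyComplexSet(
        interaction_table=table,
        sequences=sequences,
        true_interfaces=truth,
        structure_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# Interactome with planted relationships
# ---------------------------------------------------------------------------

@dataclass
class SyntheticInteractome:
    interface_maps: list[PartnerInterfaceMap]
    edge_truth: dict[tuple[str, str], Relation]
    competitive_hub_proteins: frozenset[str]
    cooperative_hub_proteins: frozenset[str]


def _interface(
    common: str, partner: str, residues: Iterable[int],
    definition: InterfaceDefinition = InterfaceDefinition.CBETA_7P5,
) -> InterfaceResidueSet:
    return InterfaceResidueSet(
        common_protein=common,
        partner_protein=partner,
        residues=frozenset(int(r) for r in residues),
        definition=definition,
    )


def _record_truth(
    truth: dict[tuple[str, str], Relation],
    a: str, b: str, relation: Relation,
) -> None:
    pair = tuple(sorted((a, b)))
    prev = truth.get(pair)
    # competitive through any common protein dominates (max-Jaccard rule)
    if prev is Relation.COMPETITIVE:
        return
    truth[pair] = relation


def generate_interactome(
    config: GeneratorConfig,
    noise_rate: float = 1.0,
    definition: InterfaceDefinition = InterfaceDefinition.CBETA_7P5,
) -> SyntheticInteractome:
    """Partner interface maps with planted competitive cliques and a
    cooperative background.

    Each of ``n_hub_clusters`` clusters holds ``cluster_size`` partner
    proteins sharing a core interface on one common protein (pairwise Jaccard
    drawn from ``planted_jaccard_levels``, all >= 0.1, hence a planted
    competitive clique).  Designated cooperative hubs reach the same degree
    through disjoint-interface pairings spread over many common proteins, and
    background common proteins contribute low-degree cooperative pairs.
    Every pair's true relation is recorded at construction time.
    """
    if any(j < 0.1 for j in config.planted_jaccard_levels):
        raise ValueError("clique Jaccard levels must be >= 0.1 to plant competition")
    rng = np.random.default_rng(config.seed)
    maps: list[PartnerInterfaceMap] = []
    truth: dict[tuple[str, str], Relation] = {}
    length = config.chain_length
    private = 4

    def disjoint_blocks(n_blocks: int, width: int = 6) -> list[range]:
        if n_blocks * width > length:
            raise ValueError("chain too short for the requested disjoint interfaces")
        return [range(1 + i * width, 1 + i * width + width) for i in range(n_blocks)]

    noise_partners: dict[str, int] = {}

    # competitive cliques around designated hubs
    for c in range(config.n_hub_clusters):
        level = config.planted_jaccard_levels[c % len(config.planted_jaccard_levels)]
        core = max(1, round(2 * private * level / (1 - level))) if level < 1 else length
        if core + config.cluster_size * private > length:
            raise ValueError("chain too short for the requested clique interfaces")
        common = f"CMN_CLQ{c:02d}"
        members = [f"CLQ{c:02d}_M{k:02d}" for k in range(config.cluster_size)]
        core_res = range(1, core + 1)
        interfaces = {}
        for k, member in enumerate(members):
            start = core + 1 + k * private
            interfaces[member] = _interface(
                common, member, list(core_res) + list(range(start, start + private)),
                definition,
            )
            noise_partners[member] = int(rng.poisson(noise_rate))
        maps.append(PartnerInterfaceMap(common_protein=common, partner_interfaces=interfaces))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                _record_truth(truth, members[i], members[j], Relation.COMPETITIVE)

    # noise: clique members also make cooperative contacts elsewhere
    for member, extra in sorted(noise_partners.items()):
        for t in range(extra):
            common = f"CMN_NZ_{member}_{t}"
            filler = f"NZ_{member}_{t}"
            blocks = disjoint_blocks(2)
            maps.append(
                PartnerInterfaceMap(
                    common_protein=common,
                    partner_interfaces={
                        member: _interface(common, member, blocks[0], definition),
                        filler: _interface(common, filler, blocks[1], definition),
                    },
                )
            )
            _record_truth(truth, member, filler, Relation.COOPERATIVE)

    # cooperative hubs: same degree as clique members, links spread out
    coop_degree = config.cluster_size - 1
    coop_hubs = [f"COOPHUB{h:02d}" for h in range(config.n_hub_clusters)]
    for h, hub in enumerate(coop_hubs):
        for t in range(coop_degree):
            common = f"CMN_CH{h:02d}_{t:02d}"
            filler = f"FILCH{h:02d}_{t:02d}"
            blocks = disjoint_blocks(2)
            maps.append(
                PartnerInterfaceMap(
                    common_protein=common,
                    partner_interfaces={
                        hub: _interface(common, hub, blocks[0], definition),
                        filler: _interface(common, filler, blocks[1], definition),
                    },
                )
            )
            _record_truth(truth, hub, filler, Relation.COOPERATIVE)

    # cooperative background
    for i in range(config.n_common_proteins):
        common = f"CMN_BG{i:03d}"
        partners = [f"BG{i:03d}_P{j}" for j in range(config.partners_per_common)]
        blocks = disjoint_blocks(len(partners))
        maps.append(
            PartnerInterfaceMap(
                common_protein=common,
                partner_interfaces={
                    p: _interface(common, p, block, definition)
                    for p, block in zip(partners, blocks)
                },
            )
        )
        for a in range(len(partners)):
            for b in range(a + 1, len(partners)):
                _record_truth(truth, partners[a], partners[b], Relation.COOPERATIVE)

    clique_members = frozenset(
        f"CLQ{c:02d}_M{k:02d}"
        for c in range(config.n_hub_clusters)
        for k in range(config.cluster_size)
    )
    return SyntheticInteractome(
        interface_maps=maps,
        edge_truth=truth,
        competitive_hub_proteins=clique_members,
        cooperative_hub_proteins=frozenset(coop_hubs),
    )


# ---------------------------------------------------------------------------
# Expression with planted pairwise correlations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpression:
    expression: pd.DataFrame  # genes x samples
    gene_map: dict[str, list[str]]
    group_rho: dict[str, float]  # protein -> planted correlation of its group


def generate_expression(
    config: GeneratorConfig,
    pair_labels: Mapping[tuple[str, str], Relation],
    one_to_many_fraction: float = 0.1,
) -> SyntheticExpression:
    """Expression profiles whose pairwise correlations follow the pair labels.

    Proteins are grouped greedily along the sorted pair list; each group g
    shares a latent factor f_g and every member's profile is
    sqrt(rho_g) * f_g + sqrt(1 - rho_g) * noise, so any two members correlate
    at rho_g in the population.  The construction is exact when the labelled
    pairs are disjoint (the benchmark case); with overlapping pairs a protein
    keeps its first group.  A ``one_to_many_fraction`` of proteins map to two
    gene IDs with independently re-noised profiles.
    """
    rng = np.random.default_rng(config.seed)
    group_of: dict[str, int] = {}
    group_rho: list[float] = []
    for pair in sorted(pair_labels):
        a, b = pair
        rho = (
            config.rho_competitive
            if Relation(pair_labels[pair]) is Relation.COMPETITIVE
            else config.rho_cooperative
        )
        if a not in group_of and b not in group_of:
            group_rho.append(rho)
            group_of[a] = group_of[b] = len(group_rho) - 1
        elif a in group_of and b not in group_of:
            group_of[b] = group_of[a]
        elif b in group_of and a not in group_of:
            group_of[a] = group_of[b]
        # both already grouped: leave as is (approximate for overlapping pairs)

    n = config.n_samples
    factors = rng.standard_normal((len(group_rho), n))
    proteins = sorted(group_of)
    gene_map: dict[str, list[str]] = {}
    rows: dict[str, np.ndarray] = {}
    many = set(
        rng.choice(
            proteins,
            size=int(round(one_to_many_fraction * len(proteins))),
            replace=False,
        )
    ) if proteins else set()
    for protein in proteins:
        g = group_of[protein]
        rho = group_rho[g]
        genes = [f"G1_{protein}"] + ([f"G2_{protein}"] if protein in many else [])
        gene_map[protein] = genes
        for gene in genes:
            noise = rng.standard_normal(n)
            rows[gene] = np.sqrt(rho) * factors[g] + np.sqrt(1 - rho) * noise
    expression = pd.DataFrame.from_dict(rows, orient="index")
    expression.columns = [f"S{j:03d}" for j in range(n)]
    return SyntheticExpression(
        expression=expression,
        gene_map=gene_map,
        group_rho={p: group_rho[g] for p, g in group_of.items()},
    )


# ---------------------------------------------------------------------------
# Annotations with planted specific domains
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAnnotations:
    focal_domain_map: dict[str, set[str]]
    reference_domain_map: dict[str, set[str]]
    reference_nodes: list[str]
    specific_domains: frozenset[str]
    specific_proteins: frozenset[str]
    isoform_counts: dict[str, int]
    essential_proteins: frozenset[str]
    domain_intervals: dict[str, list[tuple[int, int]]]
    annotation_intervals: dict[str, dict[str, list[tuple[int, int]]]]


def generate_annotations(
    config: GeneratorConfig,
    nodes: Sequence[str],
    specific_fraction: float = 0.2,
    n_shared_domains: int = 8,
    n_reference_nodes: int = 40,
    essential_rates: Mapping[str, float] | None = None,
    category_of: Mapping[str, str] | None = None,
    specific_splice_coverage: float = 0.5,
    nonspecific_splice_coverage: float = 0.2,
) -> SyntheticAnnotations:
    """Domain, isoform, essentiality and residue-interval tables.

    ``n_specific_domains`` domains are planted exclusively on a designated
    fraction of the focal nodes; a reference node set carries shared domains
    only, so the planted specific set is recoverable exactly.  Isoform counts
    follow the group-specific multi-isoform rates; alternative-splicing
    intervals cover a group-specific fraction of each protein's interaction
    domain.
    """
    if not nodes:
        raise ValueError("node set is empty")
    rng = np.random.default_rng(config.seed)
    nodes = sorted(nodes)
    n_specific = max(1, int(round(specific_fraction * len(nodes))))
    specific = set(rng.choice(nodes, size=n_specific, replace=False))
    shared = [f"DOM_SHARED{j:02d}" for j in range(n_shared_domains)]
    spec_doms = [f"DOM_SPEC{j:02d}" for j in range(config.n_specific_domains)]

    focal: dict[str, set[str]] = {}
    for p in nodes:
        focal[p] = {shared[int(rng.integers(len(shared)))]}
        if p in specific:
            focal[p].add(spec_doms[int(rng.integers(len(spec_doms)))])
            # specific proteins tend to carry more domain types
            extra = int(rng.integers(0, 3))
            for _ in range(extra):
                focal[p].add(shared[int(rng.integers(len(shared)))])
    if n_reference_nodes < n_shared_domains:
        raise ValueError("need at least one reference protein per shared domain")
    reference_nodes = [f"REF{i:03d}" for i in range(n_reference_nodes)]
    # cycle through the shared domains so every one of them genuinely occurs
    # in the reference network (otherwise it would leak into the specific set)
    reference = {
        p: {shared[i % n_shared_domains]} for i, p in enumerate(reference_nodes)
    }
    for p in reference_nodes:
        if rng.random() < 0.3:
            reference[p].add(shared[int(rng.integers(len(shared)))])

    isoform_counts: dict[str, int] = {}
    for p in nodes:
        rate = (
            config.specific_multi_isoform_rate
            if p in specific
            else config.nonspecific_multi_isoform_rate
        )
        if rng.random() < rate:
            isoform_counts[p] = 2 + int(rng.poisson(1.0))
        else:
            isoform_counts[p] = 1

    rates = dict(essential_rates or {"competitive": 0.25, "modest": 0.4, "cooperative": 0.55})
    essential = set()
    for p in nodes:
        category = (category_of or {}).get(p, "modest")
        if rng.random() < rates.get(category, 0.4):
            essential.add(p)

    domain_intervals: dict[str, list[tuple[int, int]]] = {}
    annotation_intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}
    domain_len = 40
    for p in nodes:
        start = 10
        domain_intervals[p] = [(start, start + domain_len - 1)]
        coverage = (
            specific_splice_coverage if p in specific else nonspecific_splice_coverage
        )
        covered = int(round(coverage * domain_len))
        splice = [(start, start + covered - 1)] if covered else []
        variant_covered = max(1, covered // 2)
        annotation_intervals[p] = {
            "alt_splice": splice,
            "natural_variant": [(start, start + variant_covered - 1)],
            "interaction_domain": domain_intervals[p],
        }
    return SyntheticAnnotations(
        focal_domain_map=focal,
        reference_domain_map=reference,
        reference_nodes=reference_nodes,
        specific_domains=frozenset(spec_doms),
        specific_proteins=frozenset(specific),
        isoform_counts=isoform_counts,
        essential_proteins=frozenset(essential),
        domain_intervals=domain_intervals,
        annotation_intervals=annotation_intervals,
    )


# ---------------------------------------------------------------------------
# TSV emission (the formats the pipeline readers consume)
# ---------------------------------------------------------------------------

def write_interface_maps(maps: Sequence[PartnerInterfaceMap], path: str | Path) -> None:
    from ccrn.io import write_interface_sets

    write_interface_sets(
        [s for m in maps for _, s in sorted(m.partner_interfaces.items())], path
    )


def read_interface_maps(path: str | Path) -> list[PartnerInterfaceMap]:
    from ccrn.io import interface_maps_from_sets, read_interface_sets

    return interface_maps_from_sets(read_interface_sets(path))


def write_benchmark(
    config: GeneratorConfig, out_dir: str | Path, noise_rate: float = 1.0
) -> dict[str, Path]:
    """Emit a full synthetic benchmark: interfaces, expression, annotations.

    Ground truth goes to ``out_dir/ground_truth``; everything else is written
    in the TSV formats the pipeline readers consume.  Returns the paths.
    """
    out_dir = Path(out_dir)
    truth_dir = out_dir / "ground_truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    interactome = generate_interactome(config, noise_rate=noise_rate)
    nodes = sorted({p for pair in interactome.edge_truth for p in pair})
    expression = generate_expression(config, interactome.edge_truth)
    annotations = generate_annotations(config, nodes)

    paths = {
        "interfaces": out_dir / "interfaces.tsv",
        "expression": out_dir / "expression.tsv",
        "gene_map": out_dir / "gene_map.tsv",
        "domains": out_dir / "domains.tsv",
        "reference_domains": out_dir / "reference_domains.tsv",
        "isoforms": out_dir / "isoforms.tsv",
        "essential": out_dir / "essential.tsv",
        "edge_truth": truth_dir / "edge_labels.tsv",
        "specific_truth": truth_dir / "specific_proteins.tsv",
    }
    write_interface_maps(interactome.interface_maps, paths["interfaces"])
    expression.expression.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        [(p, g) for p, gs in sorted(expression.gene_map.items()) for g in gs],
        columns=["protein_accession", "gene_id"],
    ).to_csv(paths["gene_map"], sep="\t", index=False)
    pd.DataFrame(
        [(p, d) for p, ds in sorted(annotations.focal_domain_map.items()) for d in sorted(ds)],
        columns=["protein_accession", "domain_id"],
    ).to_csv(paths["domains"], sep="\t", index=False)
    pd.DataFrame(
        [(p, d) for p, ds in sorted(annotations.reference_domain_map.items()) for d in sorted(ds)],
        columns=["protein_accession", "domain_id"],
    ).to_csv(paths["reference_domains"], sep="\t", index=False)
    pd.DataFrame(
        sorted(annotations.isoform_counts.items()),
        columns=["protein_accession", "isoform_count"],
    ).to_csv(paths["isoforms"], sep="\t", index=False)
    pd.DataFrame(
        sorted((p, int(p in annotations.essential_proteins)) for p in nodes),
        columns=["protein_accession", "essential"],
    ).to_csv(paths["essential"], sep="\t", index=False)
    pd.DataFrame(
        [(a, b, rel.value) for (a, b), rel in sorted(interactome.edge_truth.items())],
        columns=["protein_a", "protein_b", "relation"],
    ).to_csv(paths["edge_truth"], sep="\t", index=False)
    pd.DataFrame(
        sorted(annotations.specific_proteins), columns=["protein_accession"]
    ).to_csv(paths["specific_truth"], sep="\t", index=False)
    return paths
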