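"""Assemble competition-cooperation relationship networks (CCRNs).

Two partners of the same common protein are compared through the Jaccard
similarity of their interfaces on that protein.  A pair with maximal Jaccard
similarity >= 0.1 (over all shared common proteins) is *competitive* — the two
partners cannot bind simultaneously; otherwise the pair is *cooperative*.
The CCRN collects one edge per partner pair, labelled accordingly.

Species-specific proteins are those carrying a domain that occurs in the focal
network but in no protein of the reference network; removing them from the
CCRN yields the *basic* CCRN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from ccrn.structure_interfaces import InterfaceDefinition, InterfaceResidueSet

logger = logging.getLogger(__name__)

DEFAULT_JACCARD_THRESHOLD = 0.1


class Relation(str, Enum):
    COMPETITIVE = "competitive"
    COOPERATIVE = "cooperative"


@dataclass
class PartnerInterfaceMap:
    """For one common protein: the interface each partner uses on it."""

    common_protein: str
    partner_interfaces: dict[str, InterfaceResidueSet]

    def definition(self) -> InterfaceDefinition | None:
        for s in self.partner_interfaces.values():
            return s.definition
        return None


@dataclass(frozen=True)
class RelationshipEdge:
    protein_a: str
    protein_b: str
    relation: Relation
    max_jaccard: float
    evidence: tuple[tuple[str, float], ...]  # (common_protein, jaccard)

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.protein_a, self.protein_b)))


@dataclass(frozen=True)
class SpeciesSpecificSet:
    specific_domains: frozenset[str]
    specific_proteins: frozenset[str]


class CCRN:
    """Undirected bicolor graph: nodes are proteins, edges carry a relation.

    A thin wrapper over :class:`networkx.Graph` keeping the interface
    definition and Jaccard threshold that produced the network.
    """

    def __init__(
        self,
        interface_definition: InterfaceDefinition | None = None,
        jaccard_threshold: float = DEFAULT_JACCARD_THRESHOLD,
    ):
        self.graph = nx.Graph()
        self.interface_definition = (
            InterfaceDefinition(interface_definition) if interface_definition else None
        )
        self.jaccard_threshold = jaccard_threshold

    # -- construction -------------------------------------------------
    def add_edge(self, edge: RelationshipEdge) -> None:
        a, b = edge.pair
        if a == b:
            raise ValueError(f"self-edge on {a!r}")
        self.graph.add_edge(
            a,
            b,
            relation=edge.relation.value,
            max_jaccard=edge.max_jaccard,
            evidence=list(edge.evidence),
        )

    # -- queries -------------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    def edges(self, relation: Relation | None = None) -> list[RelationshipEdge]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            rel = Relation(data["relation"])
            if relation is not None and rel is not relation:
                continue
            out.append(
                RelationshipEdge(
                    protein_a=min(a, b),
                    protein_b=max(a, b),
                    relation=rel,
                    max_jaccard=data["max_jaccard"],
                    evidence=tuple(tuple(e) for e in data["evidence"]),
                )
            )
        return out

    def edge_counts(self) -> dict[str, int]:
        counts = {r.value: 0 for r in Relation}
        for _, _, data in self.graph.edges(data=True):
            counts[data["relation"]] += 1
        return counts

    def subgraph_by_relation(self, relation: Relation) -> nx.Graph:
        keep = [
            (a, b)
            for a, b, data in self.graph.edges(data=True)
            if data["relation"] == relation.value
        ]
        return self.graph.edge_subgraph(keep).copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, CCRN):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and sorted(e.pair + (e.relation.value,) for e in self.edges())
            == sorted(e.pair + (e.relation.value,) for e in other.edges())
        )

    # -- serialization -------------------------------------------------
    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "protein_a": e.protein_a,
                "protein_b": e.protein_b,
                "relation": e.relation.value,
                "max_jaccard": e.max_jaccard,
                "evidence": ";".join(f"{c}:{j:.6g}" for c, j in e.evidence),
            }
            for e in sorted(self.edges(), key=lambda e: e.pair)
        ]
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "relation", "max_jaccard", "evidence"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_edge_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        interface_definition: InterfaceDefinition | None = None,
        jaccard_threshold: float = DEFAULT_JACCARD_THRESHOLD,
    ) -> "CCRN":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        net = cls(interface_definition, jaccard_threshold)
        for row in df.itertuples(index=False):
            evidence = tuple(
                (part.rsplit(":", 1)[0], float(part.rsplit(":", 1)[1]))
                for part in str(row.evidence).split(";")
                if part
            )
            net.add_edge(
                RelationshipEdge(
                    protein_a=row.protein_a,
                    protein_b=row.protein_b,
                    relation=Relation(row.relation),
                    max_jaccard=float(row.max_jaccard),
                    evidence=evidence,
                )
            )
        return net

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in sorted(self.edges(), key=lambda e: e.pair):
                fh.write(f"{e.protein_a}\t{e.relation.value}\t{e.protein_b}\n")

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, _, data in g.edges(data=True):
            data["evidence"] = ";".join(f"{c}:{j:.6g}" for c, j in data["evidence"])
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def jaccard_interface_similarity(set_a: Iterable[int], set_b: Iterable[int]) -> float:
    """|A n B| / |A u B| for two interface residue sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(a | b)


def _pair_evidence(
    interface_maps: Sequence[PartnerInterfaceMap], protein_a: str, protein_b: str
) -> list[tuple[str, float]]:
    evidence = []
    for m in interface_maps:
        ia = m.partner_interfaces.get(protein_a)
        ib = m.partner_interfaces.get(protein_b)
        if ia is None or ib is None:
            continue
        if not ia.residues or not ib.residues:
            # an unobserved interface cannot be compared; skip this common protein
            continue
        evidence.append((m.common_protein, jaccard_interface_similarity(ia.residues, ib.residues)))
    return evidence


def classify_partner_pair(
    interface_maps: Sequence[PartnerInterfaceMap],
    protein_a: str,
    protein_b: str,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> RelationshipEdge:
    """Label one partner pair from all common proteins it shares.

    The maximal Jaccard similarity over common proteins is assigned to the
    pair; >= ``threshold`` means competitive, below means cooperative.
    """
    evidence = _pair_evidence(interface_maps, protein_a, protein_b)
    if not evidence:
        raise ValueError(
            f"{protein_a} and {protein_b} share no common protein with recorded interfaces"
        )
    max_j = max(j for _, j in evidence)
    relation = Relation.COMPETITIVE if max_j >= threshold else Relation.COOPERATIVE
    a, b = sorted((protein_a, protein_b))
    return RelationshipEdge(
        protein_a=a,
        protein_b=b,
        relation=relation,
        max_jaccard=max_j,
        evidence=tuple(evidence),
    )


def build_ccrn(
    interface_maps: Sequence[PartnerInterfaceMap],
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> CCRN:
    """Build the CCRN from per-common-protein partner interface maps.

    One edge per unordered partner pair sharing at least one common protein;
    all maps must use the same interface definition.
    """
    definitions = {m.definition() for m in interface_maps} - {None}
    if len(definitions) > 1:
        raise ValueError(f"mixed interface definitions: {sorted(d.value for d in definitions)}")
    definition = next(iter(definitions)) if definitions else None

    evidence_by_pair: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for m in interface_maps:
        usable = [
            p for p, s in m.partner_interfaces.items() if s.residues
        ]
        for p, q in combinations(sorted(usable), 2):
            j = jaccard_interface_similarity(
                m.partner_interfaces[p].residues, m.partner_interfaces[q].residues
            )
            evidence_by_pair.setdefault((p, q), []).append((m.common_protein, j))

    net = CCRN(interface_definition=definition, jaccard_threshold=threshold)
    for (a, b), evidence in sorted(evidence_by_pair.items()):
        max_j = max(j for _, j in evidence)
        relation = Relation.COMPETITIVE if max_j >= threshold else Relation.COOPERATIVE
        net.add_edge(
            RelationshipEdge(
                protein_a=a,
                protein_b=b,
                relation=relation,
                max_jaccard=max_j,
                evidence=tuple(evidence),
            )
        )
    return net


def identify_specific_proteins(
    focal_domains: Mapping[str, Iterable[str]] | pd.DataFrame,
    reference_domains: Mapping[str, Iterable[str]] | pd.DataFrame,
    focal_nodes: Iterable[str],
    reference_nodes: Iterable[str],
) -> SpeciesSpecificSet:
    """Domains found only among focal-network proteins, and their carriers.

    Domain tables are either ``{protein: [domain, ...]}`` mappings or two-column
    DataFrames (protein_accession, domain_id).  Only annotations of proteins in
    the respective node set count.
    """
    focal_nodes = set(focal_nodes)
    reference_nodes = set(reference_nodes)
    if not focal_nodes:
        raise ValueError("focal node set is empty")
    focal_map = _as_domain_map(focal_domains)
    reference_map = _as_domain_map(reference_domains)
    focal_domain_set = {
        d for p in focal_nodes for d in focal_map.get(p, ())
    }
    reference_domain_set = {
        d for p in reference_nodes for d in reference_map.get(p, ())
    }
    specific_domains = focal_domain_set - reference_domain_set
    specific_proteins = {
        p for p in focal_nodes if specific_domains & set(focal_map.get(p, ()))
    }
    return SpeciesSpecificSet(
        specific_domains=frozenset(specific_domains),
        specific_proteins=frozenset(specific_proteins),
    )


def _as_domain_map(table) -> dict[str, set[str]]:
    if isinstance(table, pd.DataFrame):
        cols = list(table.columns[:2])
        out: dict[str, set[str]] = {}
        for p, d in zip(table[cols[0]], table[cols[1]]):
            out.setdefault(str(p), set()).add(str(d))
        return out
    return {p: set(ds) for p, ds in table.items()}


def build_basic_ccrn(net: CCRN, specific_proteins: Iterable[str]) -> CCRN:
    """Remove species-specific proteins; keep the induced subgraph.

    Nodes left isolated by the removal are dropped as well, so the result is
    again a network where every node takes part in at least one relationship.
    """
    specific = set(specific_proteins)
    unknown = specific - set(net.graph.nodes)
    if unknown:
        logger.warning(
            "%d specific proteins not present in the network are ignored", len(unknown)
        )
    basic = CCRN(net.interface_definition, net.jaccard_threshold)
    for e in net.edges():
        if e.protein_a in specific or e.protein_b in specific:
            continue
        basic.add_edge(e)
    return basic
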