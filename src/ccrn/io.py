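"""Readers and writers for the pipeline's tabular and sequence inputs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from ccrn.ccrn_construction import PartnerInterfaceMap
from ccrn.structure_interfaces import InterfaceDefinition, InterfaceResidueSet

INTERACTION_COLUMNS = [
    "interaction_id", "protein_a", "protein_b", "structure_path", "chain_a", "chain_b",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Canonical sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    return df


def write_interface_sets(
    interfaces: Sequence[InterfaceResidueSet], path: str | Path
) -> None:
    rows = [
        {
            "common_protein": s.common_protein,
            "partner_protein": s.partner_protein,
            "definition": s.definition.value,
            "residues": ",".join(str(r) for r in sorted(s.residues)),
        }
        for s in interfaces
    ]
    pd.DataFrame(
        rows, columns=["common_protein", "partner_protein", "definition", "residues"]
    ).to_csv(path, sep="\t", index=False)


def read_interface_sets(path: str | Path) -> list[InterfaceResidueSet]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        residues = frozenset(
            int(r) for r in str(row.residues).split(",") if str(r).strip()
        )
        out.append(
            InterfaceResidueSet(
                common_protein=row.common_protein,
                partner_protein=row.partner_protein,
                residues=residues,
                definition=InterfaceDefinition(row.definition),
            )
        )
    return out


def interface_maps_from_sets(
    interfaces: Sequence[InterfaceResidueSet],
) -> list[PartnerInterfaceMap]:
    by_common: dict[str, dict[str, InterfaceResidueSet]] = {}
    for s in interfaces:
        by_common.setdefault(s.common_protein, {})[s.partner_protein] = s
    return [
        PartnerInterfaceMap(common_protein=c, partner_interfaces=partners)
        for c, partners in sorted(by_common.items())
    ]


def read_domain_table(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: protein_accession, domain_id (Pfam or PANTHER style)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, set[str]] = {}
    for p, d in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(p), set()).add(str(d))
    return out


def read_isoform_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return {str(p): int(c) for p, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_flag_table(path: str | Path) -> set[str]:
    """Proteins with a truthy flag in the second column (e.g. essentiality)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return {str(p) for p, flag in zip(df.iloc[:, 0], df.iloc[:, 1]) if int(flag)}


def read_gene_map(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, list[str]] = {}
    for p, g in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(p), []).append(str(g))
    return out


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_pcc_table(path: str | Path) -> dict[frozenset, float]:
    """Precomputed pairwise correlations: gene_a, gene_b, pcc."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return {
        frozenset((str(a), str(b))): float(v)
        for a, b, v in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    }
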