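"""Interface residues and buried surface area from two-chain complex structures.

Residues of one chain are *interface residues* when they lie close to the
partner chain under one of two definitions:

``cbeta_7p5``
    The residue's C-beta atom (C-alpha for glycine) is at Euclidean distance
    strictly below 7.5 angstrom from some C-beta/C-alpha of the other chain.
``heavy_4p0``
    Any heavy (non-hydrogen) atom is at most 4.0 angstrom from any heavy atom
    of the other chain.

Residue numbering is unified to canonical (UniProt-style) sequence coordinates
by global pairwise alignment of the observed chain sequence against the
canonical sequence, so that interfaces extracted from different complex
structures of the same protein are directly comparable.

Interaction strength is measured as the accessible surface area buried on
binding: dASA = ASA(chains apart) - ASA(complex), computed with the
Shrake-Rupley numerical method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

import biotite.structure as bts
import gemmi

logger = logging.getLogger(__name__)

#: Van der Waals radii (angstrom) by element symbol, Bondi-style single-atom set.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

CBETA_CUTOFF = 7.5  # strict upper bound, angstrom
HEAVY_CUTOFF = 4.0  # inclusive upper bound, angstrom


class InterfaceDefinition(str, Enum):
    """How a residue qualifies as an interface residue."""

    CBETA_7P5 = "cbeta_7p5"
    HEAVY_4P0 = "heavy_4p0"


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its residue already renumbered to canonical coordinates."""

    chain_id: str
    residue_index: int  # 1-based canonical-sequence position
    residue_name: str  # 3-letter code
    atom_name: str
    element: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError("atom coordinates must be finite")


@dataclass
class ChainStructure:
    """All atoms of one chain, in canonical residue numbering."""

    chain_id: str
    atoms: list[AtomRecord]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)


@dataclass
class ComplexStructure:
    """A binary protein-protein complex: exactly two chains, two proteins."""

    interaction_id: str
    chains: tuple[ChainStructure, ChainStructure]
    chain_to_protein: dict[str, str]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != 2 or ids[0] == ids[1]:
            raise ValueError("a complex must contain exactly two distinct chains")
        for cid in ids:
            if cid not in self.chain_to_protein:
                raise ValueError(f"chain {cid!r} missing from chain_to_protein")
        prots = [self.chain_to_protein[c] for c in ids]
        if prots[0] == prots[1]:
            raise ValueError(
                f"self-interaction ({prots[0]}): homo-oligomers are excluded"
            )


@dataclass(frozen=True)
class InterfaceResidueSet:
    """Residues on ``common_protein`` contacted by ``partner_protein``."""

    common_protein: str
    partner_protein: str
    residues: frozenset[int]
    definition: InterfaceDefinition


@dataclass(frozen=True)
class ASAResult:
    """Accessible surface areas (angstrom^2) for one binary complex."""

    interaction_id: str
    asa_unbound: float
    asa_bound: float
    delta_asa: float


# ---------------------------------------------------------------------------
# Parsing and canonical renumbering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_to_canonical(
    observed: str, canonical: str, identity_floor: float = 0.9
) -> dict[int, int]:
    """Map 0-based positions of ``observed`` to 1-based canonical positions.

    Global alignment with match +1 / mismatch -1 / gap open -5 / extend -1.
    Raises ``ValueError`` when the identity over the aligned (ungapped) region
    falls below ``identity_floor``.
    """
    if not observed or not canonical:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner()
    alignment = aligner.align(observed, canonical)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (obs_start, obs_end), (can_start, can_end) in zip(*alignment.aligned):
        for k in range(obs_end - obs_start):
            i, j = obs_start + k, can_start + k
            mapping[i] = j + 1
            aligned_cols += 1
            if observed[i] == canonical[j]:
                matches += 1
    if aligned_cols == 0 or matches / aligned_cols < identity_floor:
        frac = matches / aligned_cols if aligned_cols else 0.0
        raise ValueError(
            f"sequence identity {frac:.2f} over mapped region below the "
            f"{identity_floor} floor"
        )
    return mapping


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _best_altloc_atoms(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: the highest-occupancy alternate location."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def parse_complex(
    structure_file: str | Path,
    chain_to_protein: Mapping[str, str],
    canonical_sequences: Mapping[str, str],
    interaction_id: str | None = None,
    identity_floor: float = 0.9,
) -> ComplexStructure:
    """Read a PDB/mmCIF file and renumber both chains to canonical coordinates.

    ``chain_to_protein`` names the two chains of interest and their protein
    accessions; ``canonical_sequences`` maps accession to canonical sequence.
    Only the first model is considered; alternate conformations are resolved
    to the highest-occupancy location.  Residues that cannot be mapped onto
    the canonical sequence are dropped (and logged).
    """
    path = Path(structure_file)
    if len(chain_to_protein) != 2:
        raise ValueError("chain_to_protein must name exactly two chains")
    structure = gemmi.read_structure(str(path))
    model = structure[0]
    present = {chain.name for chain in model}
    unmapped = present - set(chain_to_protein)
    if unmapped:
        raise ValueError(
            f"{path.name} contains chains {sorted(unmapped)} not named in chain_to_protein"
        )
    chains: list[ChainStructure] = []
    for chain_id, protein in chain_to_protein.items():
        if chain_id not in present:
            raise ValueError(f"chain {chain_id!r} not found in {path.name}")
        if protein not in canonical_sequences:
            raise ValueError(f"no canonical sequence for protein {protein!r}")
        chain = model[chain_id]
        residues = [r for r in chain if any(True for _ in r)]
        observed = "".join(_one_letter(r.name) for r in residues)
        try:
            mapping = align_to_canonical(
                observed, canonical_sequences[protein], identity_floor
            )
        except ValueError as exc:
            raise ValueError(f"chain {chain_id!r}: {exc}") from exc
        atoms: list[AtomRecord] = []
        dropped = 0
        for pos, residue in enumerate(residues):
            canon = mapping.get(pos)
            if canon is None:
                dropped += 1
                continue
            for atom in _best_altloc_atoms(residue):
                atoms.append(
                    AtomRecord(
                        chain_id=chain_id,
                        residue_index=canon,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
        if dropped:
            logger.info(
                "%s chain %s: dropped %d unmappable residues", path.name, chain_id, dropped
            )
        if not atoms:
            raise ValueError(f"chain {chain_id!r} has no mappable atoms")
        chains.append(ChainStructure(chain_id=chain_id, atoms=atoms))
    return ComplexStructure(
        interaction_id=interaction_id or path.stem,
        chains=(chains[0], chains[1]),
        chain_to_protein=dict(chain_to_protein),
    )


# ---------------------------------------------------------------------------
# Interface extraction
# ---------------------------------------------------------------------------

def _representative_atoms(chain: ChainStructure) -> tuple[np.ndarray, np.ndarray]:
    """One C-beta (C-alpha for glycine, or as fallback) per residue."""
    by_residue: dict[int, dict[str, AtomRecord]] = {}
    for atom in chain.atoms:
        by_residue.setdefault(atom.residue_index, {})[atom.atom_name] = atom
    coords, resids = [], []
    for resid, atoms in sorted(by_residue.items()):
        name = next(iter(atoms.values())).residue_name
        if name == "GLY":
            rep = atoms.get("CA")
        else:
            rep = atoms.get("CB")
            if rep is None and "CA" in atoms:
                logger.warning(
                    "chain %s residue %d (%s): missing CB, falling back to CA",
                    chain.chain_id, resid, name,
                )
                rep = atoms["CA"]
        if rep is None:
            continue
        coords.append(rep.coords)
        resids.append(resid)
    if not coords:
        raise ValueError(f"chain {chain.chain_id!r} has no usable Cb/Ca atoms")
    return np.array(coords, dtype=float), np.array(resids, dtype=int)


def _heavy_atoms(chain: ChainStructure) -> tuple[np.ndarray, np.ndarray]:
    coords, resids = [], []
    for atom in chain.atoms:
        if atom.element in ("H", "D"):
            continue
        coords.append(atom.coords)
        resids.append(atom.residue_index)
    if not coords:
        raise ValueError(f"chain {chain.chain_id!r} has no heavy atoms")
    return np.array(coords, dtype=float), np.array(resids, dtype=int)


def extract_interface_residues(
    complex_structure: ComplexStructure,
    definition: InterfaceDefinition = InterfaceDefinition.CBETA_7P5,
    cutoff: float | None = None,
) -> tuple[InterfaceResidueSet, InterfaceResidueSet]:
    """Return the interface residue set on each chain of a binary complex.

    ``cutoff`` overrides the definition's default distance (7.5 strict for
    ``cbeta_7p5``, 4.0 inclusive for ``heavy_4p0``); it exists for threshold
    sensitivity scans.
    """
    definition = InterfaceDefinition(definition)
    chain_a, chain_b = complex_structure.chains
    if definition is InterfaceDefinition.CBETA_7P5:
        cut = CBETA_CUTOFF if cutoff is None else cutoff
        xa, ra = _representative_atoms(chain_a)
        xb, rb = _representative_atoms(chain_b)
        close = cdist(xa, xb) < cut  # strictly less
    else:
        cut = HEAVY_CUTOFF if cutoff is None else cutoff
        xa, ra = _heavy_atoms(chain_a)
        xb, rb = _heavy_atoms(chain_b)
        close = cdist(xa, xb) <= cut  # inclusive
    rows = close.any(axis=1)
    cols = close.any(axis=0)
    prot_a = complex_structure.chain_to_protein[chain_a.chain_id]
    prot_b = complex_structure.chain_to_protein[chain_b.chain_id]
    set_a = InterfaceResidueSet(
        common_protein=prot_a,
        partner_protein=prot_b,
        residues=frozenset(int(r) for r in np.unique(ra[rows])),
        definition=definition,
    )
    set_b = InterfaceResidueSet(
        common_protein=prot_b,
        partner_protein=prot_a,
        residues=frozenset(int(r) for r in np.unique(rb[cols])),
        definition=definition,
    )
    return set_a, set_b


# ---------------------------------------------------------------------------
# Accessible surface area
# ---------------------------------------------------------------------------

def _to_atom_array(atoms: Sequence[AtomRecord]) -> tuple[bts.AtomArray, np.ndarray]:
    arr = bts.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in atoms])
    arr.res_id = np.array([a.residue_index for a in atoms])
    arr.res_name = np.array([a.residue_name for a in atoms])
    arr.atom_name = np.array([a.atom_name for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    radii = np.array(
        [VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS) for a in atoms], dtype=float
    )
    return arr, radii


def _total_sasa(
    atoms: Sequence[AtomRecord], probe_radius: float, n_sphere_points: int
) -> float:
    arr, radii = _to_atom_array(atoms)
    per_atom = bts.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_sphere_points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    return float(np.nansum(per_atom))


def compute_asa(
    complex_structure: ComplexStructure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> ASAResult:
    """Shrake-Rupley ASA of the complex and of each chain in isolation.

    ``delta_asa = asa_unbound - asa_bound`` is the surface buried on binding
    and serves as the interaction-strength estimate.
    """
    chain_a, chain_b = complex_structure.chains
    for chain in (chain_a, chain_b):
        if not chain.atoms:
            raise ValueError(f"chain {chain.chain_id!r} has no atoms")
    unbound = _total_sasa(chain_a.atoms, probe_radius, n_sphere_points) + _total_sasa(
        chain_b.atoms, probe_radius, n_sphere_points
    )
    bound = _total_sasa(
        list(chain_a.atoms) + list(chain_b.atoms), probe_radius, n_sphere_points
    )
    return ASAResult(
        interaction_id=complex_structure.interaction_id,
        asa_unbound=unbound,
        asa_bound=bound,
        delta_asa=unbound - bound,
    )
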