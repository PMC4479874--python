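import numpy as np
import pytest

from ccrn.ccrn_construction import CCRN, Relation, RelationshipEdge
from ccrn.structure_interfaces import (
    AtomRecord,
    ChainStructure,
    ComplexStructure,
)
from ccrn.synthetic_data import GeneratorConfig, generate_toy_complexes


def make_complex(coords_a, coords_b, interaction_id="CPX", res_names=None,
                 atom_name="CB", element="C"):
    """Two-chain complex from raw coordinates, one pseudo-atom per residue."""
    def chain(chain_id, coords):
        atoms = []
        for i, xyz in enumerate(coords, start=1):
            name = (res_names or {}).get((chain_id, i), "ALA")
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_index=i,
                    residue_name=name,
                    atom_name="CA" if name == "GLY" else atom_name,
                    element=element,
                    coords=tuple(float(c) for c in xyz),
                )
            )
        return ChainStructure(chain_id=chain_id, atoms=atoms)

    return ComplexStructure(
        interaction_id=interaction_id,
        chains=(chain("A", coords_a), chain("B", coords_b)),
        chain_to_protein={"A": "PROTA", "B": "PROTB"},
    )


def bicolor_network(edges):
    """CCRN from (a, b, relation) triples with dummy evidence."""
    net = CCRN()
    for a, b, rel in edges:
        rel = Relation(rel)
        j = 0.5 if rel is Relation.COMPETITIVE else 0.0
        net.add_edge(
            RelationshipEdge(
                protein_a=min(a, b), protein_b=max(a, b), relation=rel,
                max_jaccard=j, evidence=(("CMN", j),),
            )
        )
    return net


@pytest.fixture(scope="session")
def toy_complexes(tmp_path_factory):
    cfg = GeneratorConfig(seed=11, chain_length=30)
    return generate_toy_complexes(
        cfg, tmp_path_factory.mktemp("toy"), n_complexes=3,
        contacts_per_complex=5, contact_distance=6.5,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
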