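"""Interface extraction, canonical renumbering and buried-surface-area checks."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ccrn.structure_interfaces import (
    ComplexStructure,
    InterfaceDefinition,
    align_to_canonical,
    compute_asa,
    extract_interface_residues,
    parse_complex,
)
from ccrn.synthetic_data import GeneratorConfig, generate_toy_complexes

from conftest import make_complex


# ---------------------------------------------------------------------------
# Parsing / renumbering
# ---------------------------------------------------------------------------

class TestParseComplex:
    def test_identity_mapping(self, toy_complexes):
        row = toy_complexes.interaction_table.iloc[0]
        cx = parse_complex(
            row.structure_path,
            {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
            toy_complexes.sequences,
        )
        for chain in cx.chains:
            indices = sorted({a.residue_index for a in chain.atoms})
            assert indices == list(range(1, 31))

    def test_nterminal_truncation_shifts_numbering(self, toy_complexes):
        # canonical sequence gains a 5-residue N-terminal extension: the chain
        # observed in the structure must map to canonical positions i + 5
        row = toy_complexes.interaction_table.iloc[0]
        seqs = dict(toy_complexes.sequences)
        seqs[row.protein_a] = "MKKLV" + seqs[row.protein_a]
        cx = parse_complex(
            row.structure_path,
            {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
            seqs,
        )
        chain_a = next(c for c in cx.chains if c.chain_id == row.chain_a)
        assert sorted({a.residue_index for a in chain_a.atoms}) == list(range(6, 36))

    def test_alignment_oracle_for_truncation(self):
        observed = "ACDEFGHIKL"
        canonical = "WWWWW" + observed
        mapping = align_to_canonical(observed, canonical)
        assert mapping == {i: i + 6 for i in range(10)}

    def test_unmapped_chain_in_file_is_an_error(self, tmp_path):
        # a three-chain file where the mapping names only two chains
        from ccrn.synthetic_data import _write_pseudo_pdb
        import numpy as np

        path = tmp_path / "three.pdb"
        coords = np.zeros((3, 3))
        coords[:, 1] = [0.0, 10.0, 20.0]
        _write_pseudo_pdb(
            path,
            {"A": ("AAA", coords), "B": ("AAA", coords + [50, 0, 0]),
             "C": ("AAA", coords + [100, 0, 0])},
        )
        with pytest.raises(ValueError, match="not named"):
            parse_complex(
                path,
                {"A": "P1", "B": "P2"},
                {"P1": "AAA", "P2": "AAA"},
            )

    def test_missing_chain_is_an_error(self, toy_complexes):
        row = toy_complexes.interaction_table.iloc[0]
        with pytest.raises(ValueError):
            parse_complex(
                row.structure_path,
                {"A": row.protein_a, "Z": row.protein_b},
                toy_complexes.sequences,
            )

    def test_low_identity_chain_is_an_error(self, toy_complexes):
        row = toy_complexes.interaction_table.iloc[0]
        seqs = dict(toy_complexes.sequences)
        seqs[row.protein_a] = "W" * 30  # unrelated canonical sequence
        with pytest.raises(ValueError, match="identity"):
            parse_complex(
                row.structure_path,
                {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
                seqs,
            )

    def test_self_interaction_is_rejected(self):
        with pytest.raises(ValueError, match="self-interaction"):
            cx = make_complex([(0, 0, 0)], [(10, 0, 0)])
            ComplexStructure(
                interaction_id="x",
                chains=cx.chains,
                chain_to_protein={"A": "SAME", "B": "SAME"},
            )


# ---------------------------------------------------------------------------
# Interface extraction
# ---------------------------------------------------------------------------

class TestInterfaceExtraction:
    @pytest.mark.parametrize(
        "distance,expected", [(7.4, {1}), (7.6, set()), (7.5, set())]
    )
    def test_cbeta_threshold_is_strict(self, distance, expected):
        cx = make_complex([(0, 0, 0)], [(distance, 0, 0)])
        sa, sb = extract_interface_residues(cx, InterfaceDefinition.CBETA_7P5)
        assert set(sa.residues) == expected
        assert set(sb.residues) == expected

    @pytest.mark.parametrize(
        "distance,expected", [(3.9, {1}), (4.0, {1}), (4.1, set())]
    )
    def test_heavy_threshold_is_inclusive(self, distance, expected):
        cx = make_complex([(0, 0, 0)], [(distance, 0, 0)])
        sa, sb = extract_interface_residues(cx, InterfaceDefinition.HEAVY_4P0)
        assert set(sa.residues) == expected

    def test_planted_lattice_contacts_recovered(self, toy_complexes):
        for row in toy_complexes.interaction_table.itertuples(index=False):
            cx = parse_complex(
                row.structure_path,
                {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
                toy_complexes.sequences,
            )
            sa, sb = extract_interface_residues(cx, InterfaceDefinition.CBETA_7P5)
            truth = toy_complexes.true_interfaces[row.interaction_id]
            assert set(sa.residues) == set(truth[row.protein_a])
            assert set(sb.residues) == set(truth[row.protein_b])

    def test_matches_brute_force_all_pairs(self, rng):
        # random 30 + 30 residue pseudo-structures vs a double loop oracle
        coords_a = rng.uniform(0, 30, size=(30, 3))
        coords_b = rng.uniform(0, 30, size=(30, 3))
        cx = make_complex(coords_a, coords_b)
        sa, sb = extract_interface_residues(cx, InterfaceDefinition.CBETA_7P5)
        oracle_a, oracle_b = set(), set()
        for i, xa in enumerate(coords_a, start=1):
            for j, xb in enumerate(coords_b, start=1):
                if math.dist(xa, xb) < 7.5:
                    oracle_a.add(i)
                    oracle_b.add(j)
        assert set(sa.residues) == oracle_a
        assert set(sb.residues) == oracle_b

    def test_symmetry_under_chain_swap(self, rng):
        coords_a = rng.uniform(0, 20, size=(10, 3))
        coords_b = rng.uniform(0, 20, size=(10, 3))
        cx = make_complex(coords_a, coords_b)
        swapped = ComplexStructure(
            interaction_id=cx.interaction_id,
            chains=(cx.chains[1], cx.chains[0]),
            chain_to_protein=cx.chain_to_protein,
        )
        sa, sb = extract_interface_residues(cx)
        sb2, sa2 = extract_interface_residues(swapped)
        assert sa.residues == sa2.residues
        assert sb.residues == sb2.residues

    def test_heavy_interface_monotone_in_cutoff(self, rng):
        coords_a = rng.uniform(0, 15, size=(20, 3))
        coords_b = rng.uniform(0, 15, size=(20, 3))
        cx = make_complex(coords_a, coords_b)
        sets = [
            extract_interface_residues(cx, InterfaceDefinition.HEAVY_4P0, cutoff=t)[0].residues
            for t in (3.0, 4.0, 5.0)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_cb_fallback_to_ca(self, caplog):
        # non-glycine residue providing only a CA atom is still usable
        cx = make_complex([(0, 0, 0)], [(5, 0, 0)], atom_name="CA")
        sa, _ = extract_interface_residues(cx, InterfaceDefinition.CBETA_7P5)
        assert set(sa.residues) == {1}


# ---------------------------------------------------------------------------
# Accessible surface area
# ---------------------------------------------------------------------------

def _sphere_asa(radius, probe=1.4):
    return 4 * math.pi * (radius + probe) ** 2


class TestASA:
    def test_isolated_atoms_match_closed_form(self):
        # two single-atom chains far apart: no occlusion, each is a full sphere
        cx = make_complex([(0, 0, 0)], [(100, 0, 0)])
        result = compute_asa(cx, n_sphere_points=960)
        expected = 2 * _sphere_asa(1.7)
        assert result.asa_unbound == pytest.approx(expected, rel=0.01)
        assert result.asa_bound == pytest.approx(expected, rel=0.01)
        assert result.delta_asa == pytest.approx(0.0, abs=0.5)

    def test_no_contact_means_zero_burial(self, toy_complexes):
        # 6.5 A contacts exceed 2 (r + probe) = 6.2 A: no mutual occlusion
        row = toy_complexes.interaction_table.iloc[0]
        cx = parse_complex(
            row.structure_path,
            {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
            toy_complexes.sequences,
        )
        result = compute_asa(cx)
        assert result.delta_asa == pytest.approx(0.0, abs=0.5)

    def test_partial_overlap_matches_high_resolution_oracle(self):
        # independent oracle: dense uniform sphere sampling with occlusion test
        d = 4.0
        cx = make_complex([(0, 0, 0)], [(d, 0, 0)])
        result = compute_asa(cx, n_sphere_points=960)

        def oracle_asa(center, other, radius=1.7, probe=1.4, n=100_000):
            rng = np.random.default_rng(7)
            v = rng.standard_normal((n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            points = np.asarray(center) + (radius + probe) * v
            free = np.linalg.norm(points - np.asarray(other), axis=1) >= radius + probe
            return free.mean() * _sphere_asa(radius)

        expected_bound = oracle_asa((0, 0, 0), (d, 0, 0)) + oracle_asa((d, 0, 0), (0, 0, 0))
        assert result.asa_bound == pytest.approx(expected_bound, rel=0.01)
        assert result.delta_asa > 0

    def test_burial_never_creates_surface(self, tmp_path):
        toy = generate_toy_complexes(
            GeneratorConfig(seed=23, chain_length=20), tmp_path,
            n_complexes=2, contacts_per_complex=4, contact_distance=3.9,
        )
        for row in toy.interaction_table.itertuples(index=False):
            cx = parse_complex(
                row.structure_path,
                {row.chain_a: row.protein_a, row.chain_b: row.protein_b},
                toy.sequences,
            )
            result = compute_asa(cx)
            assert result.asa_bound <= result.asa_unbound + 0.01
            assert result.delta_asa == pytest.approx(
                result.asa_unbound - result.asa_bound
            )

    def test_delta_asa_symmetric_under_chain_swap(self):
        cx = make_complex([(0, 0, 0), (0, 5, 0)], [(4, 0, 0)])
        swapped = ComplexStructure(
            interaction_id=cx.interaction_id,
            chains=(cx.chains[1], cx.chains[0]),
            chain_to_protein=cx.chain_to_protein,
        )
        assert compute_asa(cx).delta_asa == pytest.approx(
            compute_asa(swapped).delta_asa, abs=1e-3
        )
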