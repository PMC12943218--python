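"""Interaction profiler: boundary behavior, oracle equivalence, invariances."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_complex
from flavoscreen.interactions import (
    AROMATIC_RING_ATOMS,
    BACKBONE_ATOMS,
    InteractionCriteria,
    check_reference_interactions,
    find_hbonds,
    find_hydrophobic,
    find_pi_stacking,
    profile_complex,
)
from flavoscreen.structures import (
    Atom,
    ComplexStructure,
    LigandMolecule,
    ProteinStructure,
    Residue,
)
from flavoscreen.synthetic import PlantSpec, gen_planted_complex

CRIT = InteractionCriteria()


# ---------------------------------------------------------------------------
# Independent brute-force oracle: pure-python all-pairs scan, no numpy
# vectorization, classification re-derived from the stated rules.
# ---------------------------------------------------------------------------

def brute_force_profile(complex_, criteria):
    hb, pi, hp = set(), set(), set()
    for res in complex_.protein.residues:
        for pa in res.atoms:
            for la in complex_.ligand.atoms:
                d = math.dist(tuple(la.coords), tuple(pa.coords))
                if (la.element in ("N", "O") and pa.element in ("N", "O")
                        and d <= criteria.hbond_cutoff):
                    hb.add(res.residue_id)
                if (la.element == "C" and pa.element == "C"
                        and res.name in criteria.hydrophobic_residues
                        and pa.name not in BACKBONE_ATOMS
                        and d <= criteria.hydrophobic_cutoff):
                    hp.add(res.residue_id)
                if (res.name in criteria.aromatic_residues
                        and pa.name in AROMATIC_RING_ATOMS.get(res.name, ())
                        and la.element != "H"
                        and d <= criteria.pistack_cutoff):
                    pi.add(res.residue_id)
    return hb, pi, hp


def random_complex(seed, n_residues=12, n_ligand_atoms=10, box=14.0):
    rng = np.random.default_rng(seed)
    templates = {
        "ASN": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")],
        "SER": [("CB", "C"), ("OG", "O")],
        "LEU": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")],
        "PHE": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"),
                ("CE1", "C"), ("CE2", "C"), ("CZ", "C")],
        "TRP": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("NE1", "N"),
                ("CE2", "C"), ("CZ2", "C"), ("CH2", "C")],
        "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    }
    names = list(templates)
    serial = iter(range(1, 10000))
    residues = []
    for i in range(n_residues):
        resname = names[rng.integers(len(names))]
        center = rng.uniform(0, box, 3)
        atoms = [
            Atom(next(serial), atname, element,
                 center + rng.uniform(-1.5, 1.5, 3))
            for atname, element in templates[resname]
        ]
        residues.append(Residue(resname, "A", i + 1, atoms))
    lig_elements = ["C", "C", "C", "O", "N"]
    ligand_atoms = [
        Atom(next(serial), f"L{j}", lig_elements[rng.integers(5)],
             rng.uniform(0, box, 3), aromatic_flag=bool(rng.integers(2)))
        for j in range(n_ligand_atoms)
    ]
    return ComplexStructure(ProteinStructure(residues),
                            LigandMolecule("lig", atoms=ligand_atoms))


# ---------------------------------------------------------------------------
# Boundary examples
# ---------------------------------------------------------------------------

class TestHbondBoundaries:
    @pytest.mark.parametrize("z, expected", [(3.4, 1), (3.5, 1), (3.6, 0)])
    def test_cutoff_is_inclusive(self, z, expected):
        cx = make_complex(
            [("ASN", 458, [("N", "N", (0, 0, z))])],
            [("O1", "O", (0, 0, 0))],
        )
        assert len(find_hbonds(cx, CRIT)) == expected

    def test_carbon_pairs_are_not_hbonds(self):
        cx = make_complex(
            [("ASN", 458, [("CB", "C", (0, 0, 2.0))])],
            [("C1", "C", (0, 0, 0))],
        )
        assert find_hbonds(cx, CRIT) == []

    def test_angle_mode_rejects_bent_geometry(self):
        # donor O-H pointing away from the acceptor: D-H...A angle ~0
        cx = make_complex(
            [("ASN", 458, [("OD1", "O", (0, 0, 3.0))])],
            [("O1", "O", (0, 0, 0)), ("H1", "H", (0, 0, -1.0))],
        )
        assert len(find_hbonds(cx, CRIT)) == 1
        assert find_hbonds(cx, CRIT, angle_mode=True) == []

    def test_angle_mode_accepts_linear_geometry(self):
        # H between donor and acceptor: D-H...A angle 180
        cx = make_complex(
            [("ASN", 458, [("OD1", "O", (0, 0, 3.0))])],
            [("O1", "O", (0, 0, 0)), ("H1", "H", (0, 0, 1.0))],
        )
        assert len(find_hbonds(cx, CRIT, angle_mode=True)) == 1

    def test_angle_mode_without_hydrogens_falls_back_to_distance(self):
        cx = make_complex(
            [("ASN", 458, [("OD1", "O", (0, 0, 3.0))])],
            [("O1", "O", (0, 0, 0))],
        )
        assert len(find_hbonds(cx, CRIT, angle_mode=True)) == 1


class TestHydrophobicBoundaries:
    def test_leu_carbon_within_cutoff(self):
        cx = make_complex(
            [("LEU", 182, [("CD1", "C", (0, 0, 3.9))])],
            [("C1", "C", (0, 0, 0))],
        )
        assert len(find_hydrophobic(cx, CRIT)) == 1

    def test_unlisted_residue_ignored(self):
        cx = make_complex(
            [("SER", 183, [("OG", "O", (0, 0, 3.9)), ("CB", "C", (0, 0, 3.9))])],
            [("C1", "C", (0, 0, 0))],
        )
        assert find_hydrophobic(cx, CRIT) == []

    def test_beyond_cutoff_excluded(self):
        cx = make_complex(
            [("LEU", 182, [("CD1", "C", (0, 0, 4.2))])],
            [("C1", "C", (0, 0, 0))],
        )
        assert find_hydrophobic(cx, CRIT) == []

    def test_backbone_carbons_excluded(self):
        cx = make_complex(
            [("LEU", 182, [("CA", "C", (0, 0, 3.0)), ("C", "C", (0, 0, 3.0))])],
            [("C1", "C", (0, 0, 0))],
        )
        assert find_hydrophobic(cx, CRIT) == []


class TestPiStackingBoundaries:
    @pytest.mark.parametrize("z, expected", [(5.0, 1), (5.4, 1), (5.6, 0)])
    def test_distance_window(self, z, expected):
        cx = make_complex(
            [("PHE", 435, [("CZ", "C", (0, 0, z))])],
            [("C1", "C", (0, 0, 0), True)],
        )
        assert len(find_pi_stacking(cx, CRIT)) == expected

    def test_tyr_ring_atom_counts(self):
        cx = make_complex(
            [("TYR", 327, [("CE1", "C", (0, 0, 5.4))])],
            [("C1", "C", (0, 0, 0))],
        )
        assert len(find_pi_stacking(cx, CRIT)) == 1

    def test_tyr_hydroxyl_oxygen_is_not_ring(self):
        cx = make_complex(
            [("TYR", 327, [("OH", "O", (0, 0, 5.0))])],
            [("C1", "C", (0, 0, 4.0))],
        )
        assert find_pi_stacking(cx, CRIT) == []

    def test_strict_mode_needs_aromatic_flag(self):
        cx = make_complex(
            [("PHE", 435, [("CZ", "C", (0, 0, 5.0))])],
            [("C1", "C", (0, 0, 0), False)],
        )
        assert len(find_pi_stacking(cx, CRIT)) == 1
        assert find_pi_stacking(cx, CRIT, strict=True) == []


class TestProfileAggregation:
    def test_planted_counts(self):
        cx, expected = gen_planted_complex(
            PlantSpec(n_hbonds=2, n_pistacks=1, n_hydrophobic=0, seed=7)
        )
        assert profile_complex(cx).counts == (2, 1, 0)

    def test_distant_ligand_gives_empty_profile(self):
        cx = make_complex(
            [("ASN", 458, [("OD1", "O", (0, 0, 0))])],
            [("O1", "O", (100.0, 0, 0))],
        )
        profile = profile_complex(cx)
        assert profile.counts == (0, 0, 0) and profile.raw_contacts == []

    def test_residue_can_appear_under_multiple_types(self):
        # TRP NE1 is both polar and a ring atom
        cx = make_complex(
            [("TRP", 459, [("NE1", "N", (0, 0, 3.0))])],
            [("O1", "O", (0, 0, 0)), ("C1", "C", (0.5, 0, 0))],
        )
        profile = profile_complex(cx)
        assert profile.hbond_residues == ["TRP459"]
        assert profile.pistack_residues == ["TRP459"]

    def test_residue_lists_sorted_and_unique(self):
        cx, _ = gen_planted_complex(PlantSpec(n_hbonds=3, seed=3))
        profile = profile_complex(cx)
        assert profile.hbond_residues == sorted(set(profile.hbond_residues),
                                                key=lambda r: int(r[3:]))


class TestReferenceCheck:
    def test_crystallographic_anchor_residues_pass(self):
        cx = make_complex(
            [("ASN", 458, [("OD1", "O", (0, 0, 0))]),
             ("TRP", 459, [("NE1", "N", (10, 0, 0))])],
            [("O1", "O", (0, 0, 3.0)), ("O2", "O", (10, 0, 3.0))],
        )
        ok, missing = check_reference_interactions(
            profile_complex(cx), {"ASN458", "TRP459"}
        )
        assert ok and not missing

    def test_missing_residue_reported(self):
        cx = make_complex(
            [("GLY", 1, [("O", "O", (50, 0, 0))])],
            [("O1", "O", (0, 0, 0))],
        )
        ok, missing = check_reference_interactions(profile_complex(cx),
                                                   {"ASN458"})
        assert not ok and missing == {"ASN458"}

    def test_empty_requirement_passes_vacuously(self):
        cx = make_complex([("GLY", 1, [("O", "O", (50, 0, 0))])],
                          [("O1", "O", (0, 0, 0))])
        ok, missing = check_reference_interactions(profile_complex(cx), set())
        assert ok and missing == set()


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_profiler_matches_brute_force_oracle(seed):
    cx = random_complex(seed)
    profile = profile_complex(cx)
    hb, pi, hp = brute_force_profile(cx, CRIT)
    assert set(profile.hbond_residues) == hb
    assert set(profile.pistack_residues) == pi
    assert set(profile.hydrophobic_residues) == hp


@pytest.mark.parametrize("seed", range(4))
def test_cutoff_monotonicity(seed):
    cx = random_complex(seed, box=10.0)
    small = InteractionCriteria(hbond_cutoff=2.5, hydrophobic_cutoff=3.0,
                                pistack_cutoff=4.0)
    p_small = profile_complex(cx, small)
    p_large = profile_complex(cx, CRIT)
    assert set(p_small.hbond_residues) <= set(p_large.hbond_residues)
    assert set(p_small.pistack_residues) <= set(p_large.pistack_residues)
    assert set(p_small.hydrophobic_residues) <= set(p_large.hydrophobic_residues)


@pytest.mark.parametrize("seed", range(4))
def test_rigid_invariance(seed):
    cx = random_complex(seed)
    rot = Rotation.random(random_state=seed).as_matrix()
    shift = np.array([5.0, -3.0, 12.0])

    def transform(complex_):
        residues = [
            Residue(r.name, r.chain, r.number, [
                Atom(a.serial, a.name, a.element, rot @ a.coords + shift,
                     aromatic_flag=a.aromatic_flag)
                for a in r.atoms
            ])
            for r in complex_.protein.residues
        ]
        lig = [Atom(a.serial, a.name, a.element, rot @ a.coords + shift,
                    aromatic_flag=a.aromatic_flag)
               for a in complex_.ligand.atoms]
        return ComplexStructure(ProteinStructure(residues),
                                LigandMolecule("lig", atoms=lig))

    before = profile_complex(cx)
    after = profile_complex(transform(cx))
    assert before.hbond_residues == after.hbond_residues
    assert before.pistack_residues == after.pistack_residues
    assert before.hydrophobic_residues == after.hydrophobic_residues


def test_contact_distances_respect_cutoffs():
    cx = random_complex(99)
    profile = profile_complex(cx)
    cutoff = {"hbond": CRIT.hbond_cutoff, "pistack": CRIT.pistack_cutoff,
              "hydrophobic": CRIT.hydrophobic_cutoff}
    for contact in profile.raw_contacts:
        assert contact.distance <= cutoff[contact.kind]
    # every listed residue is witnessed by a raw contact of that type
    for kind, listed in (("hbond", profile.hbond_residues),
                         ("pistack", profile.pistack_residues),
                         ("hydrophobic", profile.hydrophobic_residues)):
        witnessed = {c.residue_id for c in profile.contacts_of_kind(kind)}
        assert set(listed) == witnessed
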