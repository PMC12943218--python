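import numpy as np
import pytest

from flavoscreen.structures import (
    Atom,
    ComplexStructure,
    LigandMolecule,
    ProteinStructure,
    Residue,
)


def make_atom(serial, name, element, xyz, aromatic=False):
    return Atom(serial, name, element, np.asarray(xyz, dtype=float),
                aromatic_flag=aromatic)


def make_complex(residue_specs, ligand_specs):
    """Build a complex from terse specs.

    residue_specs: list of (resname, number, [(atom name, element, xyz), ...])
    ligand_specs:  list of (atom name, element, xyz[, aromatic])
    """
    serial = iter(range(1, 10000))
    residues = [
        Residue(resname, "A", number,
                [make_atom(next(serial), n, e, xyz) for n, e, xyz in atoms])
        for resname, number, atoms in residue_specs
    ]
    ligand_atoms = [
        make_atom(next(serial), s[0], s[1], s[2],
                  aromatic=(s[3] if len(s) > 3 else False))
        for s in ligand_specs
    ]
    return ComplexStructure(
        ProteinStructure(residues),
        LigandMolecule("lig", atoms=ligand_atoms),
    )


@pytest.fixture
def asn_hbond_complex():
    """Ligand oxygen 3.0 A from an ASN OD1; nothing else in range."""
    return make_complex(
        [("ASN", 458, [("CB", "C", (0.0, 0.0, -1.4)),
                       ("OD1", "O", (0.0, 0.0, 0.0)),
                       ("ND2", "N", (0.0, 0.0, -2.8))])],
        [("O1", "O", (0.0, 0.0, 3.0))],
    )
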