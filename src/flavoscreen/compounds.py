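"""Embedded fixtures for the eight screened flavonoids.

Each entry carries the PubChem CID, canonical SMILES, and molecular formula
of one compound from the screening panel, plus the best Vina binding
affinity (kcal/mol) reported for it against the GLUT9 urate transporter.
Fixtures are resolved offline by name or CID; nothing is fetched at runtime.
"""

from __future__ import annotations

from .structures import LigandMolecule

__all__ = [
    "FLAVONOID_FIXTURES",
    "REFERENCE_BINDING_AFFINITIES",
    "load_ligand_fixture",
    "known_fixture_names",
]

# name -> (CID, canonical SMILES, molecular formula)
FLAVONOID_FIXTURES: dict[str, tuple[int, str, str]] = {
    "apigenin": (
        5280443,
        "C1=CC(=CC=C1C2=CC(=O)C3=C(C=C(C=C3O2)O)O)O",
        "C15H10O5",
    ),
    "chrysin": (
        5281607,
        "C1=CC=C(C=C1)C2=CC(=O)C3=C(C=C(C=C3O2)O)O",
        "C15H10O4",
    ),
    "quercetin": (
        5280343,
        "C1=CC(=C(C=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O)O",
        "C15H10O7",
    ),
    "kaempferol": (
        5280863,
        "C1=CC(=CC=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O",
        "C15H10O6",
    ),
    "luteolin": (
        5280445,
        "C1=CC(=C(C=C1C2=CC(=O)C3=C(C=C(C=C3O2)O)O)O)O",
        "C15H10O6",
    ),
    "myricetin": (
        5281672,
        "C1=C(C=C(C(=C1O)O)O)C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O",
        "C15H10O8",
    ),
    "naringenin": (
        439246,
        "C1[C@@H](OC2=CC(=CC(=C2C1=O)O)O)C3=CC=C(C=C3)O",
        "C15H12O5",
    ),
    "egcg": (
        65064,
        "C1[C@H]([C@H](OC2=CC(=CC(=C21)O)O)C3=CC(=C(C(=C3)O)O)O)"
        "OC(=O)C4=CC(=C(C(=C4)O)O)O",
        "C22H18O11",
    ),
}

#: Best docked Vina affinity (kcal/mol) per compound against GLUT9; input
#: data for ranking reports and pose-selection checks.
REFERENCE_BINDING_AFFINITIES: dict[str, float] = {
    "egcg": -9.10,
    "chrysin": -8.35,
    "apigenin": -8.04,
    "luteolin": -8.01,
    "naringenin": -7.96,
    "myricetin": -7.84,
    "quercetin": -7.69,
    "kaempferol": -7.67,
}

_BY_CID = {cid: name for name, (cid, _, _) in FLAVONOID_FIXTURES.items()}


def known_fixture_names() -> list[str]:
    return sorted(FLAVONOID_FIXTURES)


def load_ligand_fixture(name_or_cid: str | int) -> LigandMolecule:
    """Resolve one of the eight packaged flavonoids by name or PubChem CID.

    Raises ``KeyError`` listing the known fixtures for anything else.
    """
    key = str(name_or_cid).strip().lower()
    if key.isdigit() and int(key) in _BY_CID:
        key = _BY_CID[int(key)]
    if key not in FLAVONOID_FIXTURES:
        raise KeyError(
            f"unknown compound {name_or_cid!r}; known fixtures: "
            f"{', '.join(known_fixture_names())}"
        )
    cid, smiles, formula = FLAVONOID_FIXTURES[key]
    return LigandMolecule(name=key, cid=cid, smiles=smiles, formula=formula)
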