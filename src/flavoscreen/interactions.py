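"""Distance-based protein-ligand interaction classifier.

Assigns per-residue hydrogen-bond, hydrophobic, and pi-stacking contacts
from a docked complex using pure distance criteria:

* hydrogen bonds: polar (N, O) ligand atoms within 3.5 A of polar protein
  atoms. An optional angle mode additionally requires a donor-H...acceptor
  angle >= 120 degrees whenever the donor carries an explicit hydrogen,
  matching the common visualization-software criterion; the default is
  distance-only because docked poses cannot be assumed to carry hydrogens.
* hydrophobic contacts: ligand carbons within 4.0 A of side-chain carbons of
  PHE, TRP, TYR, LEU, ILE, VAL, ALA, MET, or PRO.
* pi-stacking: any ligand atom within 5.5 A of an aromatic ring atom of PHE,
  TRP, or TYR (literal mode); strict mode restricts the ligand side to atoms
  flagged aromatic. No ring-plane angle test is applied in either mode.

All cutoffs are inclusive (<=). Residues are reported as NAME+number
(e.g. ASN458), once per interaction type, sorted by (chain, number).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, ComplexStructure, Residue

__all__ = [
    "InteractionCriteria",
    "Contact",
    "InteractionProfile",
    "find_hbonds",
    "find_hydrophobic",
    "find_pi_stacking",
    "profile_complex",
    "check_reference_interactions",
    "AROMATIC_RING_ATOMS",
]

#: Ring-atom names per aromatic residue (TYR hydroxyl O excluded).
AROMATIC_RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset(
        {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}
    ),
}

#: Backbone atom names; everything else in a residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Maximum donor-hydrogen covalent distance (A) used to attach explicit
#: hydrogens to their donor heavy atom in angle mode.
_DH_COVALENT_MAX = 1.3


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs and residue classes for contact assignment."""

    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 4.0
    pistack_cutoff: float = 5.5
    hbond_angle_min: float = 120.0
    hydrophobic_residues: frozenset[str] = frozenset(
        {"PHE", "TRP", "TYR", "LEU", "ILE", "VAL", "ALA", "MET", "PRO"}
    )
    aromatic_residues: frozenset[str] = frozenset({"PHE", "TRP", "TYR"})

    def __post_init__(self) -> None:
        for label in ("hbond_cutoff", "hydrophobic_cutoff", "pistack_cutoff"):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be positive")


@dataclass(frozen=True)
class Contact:
    ligand_atom: Atom
    protein_atom: Atom
    residue: Residue
    distance: float
    kind: str  # "hbond" | "hydrophobic" | "pistack"

    @property
    def residue_id(self) -> str:
        return self.residue.residue_id


@dataclass
class InteractionProfile:
    hbond_residues: list[str] = field(default_factory=list)
    pistack_residues: list[str] = field(default_factory=list)
    hydrophobic_residues: list[str] = field(default_factory=list)
    raw_contacts: list[Contact] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n hbond residues, n pi-stacking residues, n hydrophobic residues)."""
        return (
            len(self.hbond_residues),
            len(self.pistack_residues),
            len(self.hydrophobic_residues),
        )

    def contacts_of_kind(self, kind: str) -> list[Contact]:
        return [c for c in self.raw_contacts if c.kind == kind]


def _distance(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


def _attached_hydrogens(atom: Atom, pool: list[Atom]) -> list[Atom]:
    return [
        h for h in pool
        if h.is_hydrogen and _distance(atom, h) <= _DH_COVALENT_MAX
    ]


def _dha_angle(donor: Atom, hydrogen: Atom, acceptor: Atom) -> float:
    """Donor-H...acceptor angle at the hydrogen, in degrees."""
    v1 = donor.coords - hydrogen.coords
    v2 = acceptor.coords - hydrogen.coords
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hbonds(
    complex_: ComplexStructure,
    criteria: InteractionCriteria = InteractionCriteria(),
    angle_mode: bool = False,
) -> list[Contact]:
    """Polar-polar ligand/protein pairs within the H-bond distance cutoff.

    In angle mode, a pair in which either partner carries an explicit
    hydrogen must additionally satisfy a donor-H...acceptor angle of at
    least ``criteria.hbond_angle_min`` (best over attached hydrogens);
    pairs with no explicit hydrogens are accepted on distance alone.
    """
    contacts: list[Contact] = []
    lig_atoms = complex_.ligand.atoms or []
    lig_polar = [a for a in lig_atoms if a.is_polar]
    for res in complex_.protein.residues:
        prot_polar = [a for a in res.atoms if a.is_polar]
        for la in lig_polar:
            for pa in prot_polar:
                d = _distance(la, pa)
                if d > criteria.hbond_cutoff:
                    continue
                if angle_mode:
                    ok = True
                    lig_hs = _attached_hydrogens(la, lig_atoms)
                    prot_hs = _attached_hydrogens(pa, res.atoms)
                    if lig_hs or prot_hs:
                        angles = [_dha_angle(la, h, pa) for h in lig_hs]
                        angles += [_dha_angle(pa, h, la) for h in prot_hs]
                        ok = max(angles) >= criteria.hbond_angle_min
                    if not ok:
                        continue
                contacts.append(Contact(la, pa, res, d, "hbond"))
    return contacts


def find_hydrophobic(
    complex_: ComplexStructure,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[Contact]:
    """Ligand carbon / hydrophobic-residue side-chain carbon pairs <= cutoff."""
    contacts: list[Contact] = []
    lig_carbons = [a for a in (complex_.ligand.atoms or []) if a.is_carbon]
    for res in complex_.protein.residues:
        if res.name not in criteria.hydrophobic_residues:
            continue
        side_carbons = [
            a for a in res.atoms
            if a.is_carbon and a.name.upper() not in BACKBONE_ATOMS
        ]
        for la in lig_carbons:
            for pa in side_carbons:
                d = _distance(la, pa)
                if d <= criteria.hydrophobic_cutoff:
                    contacts.append(Contact(la, pa, res, d, "hydrophobic"))
    return contacts


def find_pi_stacking(
    complex_: ComplexStructure,
    criteria: InteractionCriteria = InteractionCriteria(),
    strict: bool = False,
) -> list[Contact]:
    """Ligand atoms within the pi-stacking cutoff of aromatic ring atoms.

    Strict mode requires the ligand atom to be flagged as aromatic; the
    default accepts any ligand atom.
    """
    contacts: list[Contact] = []
    lig_atoms = [
        a for a in (complex_.ligand.atoms or [])
        if (a.aromatic_flag if strict else True) and not a.is_hydrogen
    ]
    for res in complex_.protein.residues:
        if res.name not in criteria.aromatic_residues:
            continue
        ring_names = AROMATIC_RING_ATOMS.get(res.name, frozenset())
        ring_atoms = [a for a in res.atoms if a.name.upper() in ring_names]
        for la in lig_atoms:
            for pa in ring_atoms:
                d = _distance(la, pa)
                if d <= criteria.pistack_cutoff:
                    contacts.append(Contact(la, pa, res, d, "pistack"))
    return contacts


def _residue_ids_sorted(contacts: list[Contact]) -> list[str]:
    seen: dict[str, tuple[str, int]] = {}
    for c in contacts:
        seen.setdefault(c.residue_id, (c.residue.chain, c.residue.number))
    return sorted(seen, key=lambda rid: seen[rid])


def profile_complex(
    complex_: ComplexStructure,
    criteria: InteractionCriteria = InteractionCriteria(),
    angle_mode: bool = False,
    strict_pi: bool = False,
) -> InteractionProfile:
    """Aggregate the three contact finders into a per-residue profile.

    A residue may appear under several interaction types; within a type it
    is listed once, sorted by (chain, residue number).
    """
    hb = find_hbonds(complex_, criteria, angle_mode=angle_mode)
    pi = find_pi_stacking(complex_, criteria, strict=strict_pi)
    hp = find_hydrophobic(complex_, criteria)
    return InteractionProfile(
        hbond_residues=_residue_ids_sorted(hb),
        pistack_residues=_residue_ids_sorted(pi),
        hydrophobic_residues=_residue_ids_sorted(hp),
        raw_contacts=hb + pi + hp,
    )


def check_reference_interactions(
    profile: InteractionProfile, required: set[str]
) -> tuple[bool, set[str]]:
    """Check that all required residues appear among the H-bond residues.

    Returns (ok, missing). Used to validate a docked pose against a known
    binding mode (e.g. the crystallographic apigenin contacts ASN458 and
    TRP459).
    """
    missing = set(required) - set(profile.hbond_residues)
    return (not missing, missing)
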