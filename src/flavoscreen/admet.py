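"""Molecular descriptors and rule-based drug-likeness classification.

Descriptors come from RDKit on canonical SMILES: molecular weight, Crippen
LogP, Lipinski-style donor/acceptor counts (HBD = O-H/N-H groups, HBA =
N + O atoms), Ertl TPSA, and rotatable bonds. The rule engine applies:

* Lipinski's Rule of Five: violations counted for MW > 500, LogP > 5,
  HBD > 5, HBA > 10. The pass flag requires zero violations and the
  violation count is always reported alongside, so the classic
  at-most-one-violation convention is recoverable.
* GI absorption: High iff TPSA <= 140 A^2.
* Blood-brain barrier: Yes iff TPSA <= 90 A^2 and MW <= 450 g/mol.

All boundaries are inclusive on the passing side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .structures import LigandMolecule

__all__ = [
    "DescriptorSet",
    "AdmetVerdict",
    "mw_from_formula",
    "compute_descriptors",
    "count_lipinski_violations",
    "classify_gi_absorption",
    "classify_bbb",
    "classify_admet",
    "build_admet_table",
]

#: IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Br": 79.904,
    "I": 126.90, "Fe": 55.845, "Zn": 65.38,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class DescriptorSet:
    mw: float       # g/mol
    logp: float     # Crippen
    hbd: int        # O-H + N-H count
    hba: int        # N + O count
    tpsa: float     # A^2
    rot_bonds: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        if min(self.hbd, self.hba, self.rot_bonds) < 0 or self.tpsa < 0:
            raise ValueError("counts and TPSA must be non-negative")


@dataclass(frozen=True)
class AdmetVerdict:
    lipinski_violations: int
    lipinski_pass: bool
    gi_absorption: str  # "High" | "Low"
    bbb: str            # "Yes" | "No"

    @property
    def lipinski_label(self) -> str:
        """Table-style label: 'Yes' or 'No (k)' with the violation count."""
        if self.lipinski_pass:
            return "Yes"
        return f"No ({self.lipinski_violations})"


def mw_from_formula(formula: str) -> float:
    """Molecular weight (g/mol) from a Hill-style formula, e.g. C22H18O11.

    Uses IUPAC standard atomic weights; the result is rounded to 2 decimals
    (presentation precision of formula-based tables).
    """
    pos = 0
    total = 0.0
    matched_any = False
    for m in _FORMULA_TOKEN.finditer(formula.strip()):
        if m.start() != pos or not m.group(0):
            break
        pos = m.end()
        matched_any = True
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
        total += ATOMIC_WEIGHTS[element] * count
    if not matched_any or pos != len(formula.strip()):
        raise ValueError(f"malformed molecular formula {formula!r}")
    return round(total, 2)


def _mol_from_ligand(molecule: LigandMolecule) -> Chem.Mol:
    if not molecule.smiles:
        raise ValueError(
            f"ligand {molecule.name!r} has no SMILES; descriptors need a "
            "connection table"
        )
    mol = Chem.MolFromSmiles(molecule.smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for {molecule.name!r}: "
                         f"{molecule.smiles!r}")
    return mol


def compute_descriptors(molecule: LigandMolecule) -> DescriptorSet:
    """Physicochemical descriptor set from the molecule's canonical SMILES."""
    mol = _mol_from_ligand(molecule)
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        rot_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
    )


def count_lipinski_violations(d: DescriptorSet) -> int:
    """Number of Rule-of-Five criteria violated (strict > on each bound)."""
    return sum([d.mw > 500.0, d.logp > 5.0, d.hbd > 5, d.hba > 10])


def classify_gi_absorption(tpsa: float) -> str:
    """'High' gastrointestinal absorption iff TPSA <= 140 A^2."""
    if tpsa < 0:
        raise ValueError("TPSA must be non-negative")
    return "High" if tpsa <= 140.0 else "Low"


def classify_bbb(tpsa: float, mw: float) -> str:
    """'Yes' for predicted BBB permeation iff TPSA <= 90 A^2 and MW <= 450."""
    return "Yes" if (tpsa <= 90.0 and mw <= 450.0) else "No"


def classify_admet(d: DescriptorSet) -> AdmetVerdict:
    violations = count_lipinski_violations(d)
    return AdmetVerdict(
        lipinski_violations=violations,
        lipinski_pass=violations == 0,
        gi_absorption=classify_gi_absorption(d.tpsa),
        bbb=classify_bbb(d.tpsa, d.mw),
    )


ADMET_COLUMNS = [
    "Compound", "MW (g/mol)", "LogP", "HBD", "HBA", "TPSA (A^2)",
    "Rot. Bonds", "Lipinski", "GI Absorption", "BBB",
]


def build_admet_table(molecules: list[LigandMolecule]) -> pd.DataFrame:
    """One descriptor + verdict row per molecule, screening-table layout.

    Per-row failures are propagated with the offending compound named.
    """
    rows = []
    for mol in molecules:
        try:
            d = compute_descriptors(mol)
            v = classify_admet(d)
        except ValueError as exc:
            raise ValueError(f"{mol.name}: {exc}") from exc
        rows.append({
            "Compound": mol.name,
            "MW (g/mol)": round(d.mw, 2),
            "LogP": round(d.logp, 2),
            "HBD": d.hbd,
            "HBA": d.hba,
            "TPSA (A^2)": round(d.tpsa, 2),
            "Rot. Bonds": d.rot_bonds,
            "Lipinski": v.lipinski_label,
            "GI Absorption": v.gi_absorption,
            "BBB": v.bbb,
        })
    return pd.DataFrame(rows, columns=ADMET_COLUMNS)
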