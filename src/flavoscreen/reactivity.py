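"""Conceptual-DFT global reactivity descriptors via Koopmans' theorem.

From frontier-orbital energies in eV:

    I  = -E(HOMO)            ionization potential
    A  = -E(LUMO)            electron affinity
    chi = (I + A) / 2        electronegativity
    eta = (I - A) / 2        chemical hardness
    S  = 1 / (2 eta)         chemical softness (eV^-1)
    omega = chi^2 / (2 eta)  electrophilicity index
    dE = E(LUMO) - E(HOMO)   HOMO-LUMO gap

The module also embeds the published B3LYP/6-31G(d) frontier-orbital
energies for EGCG, chrysin, and apigenin as reference inputs, so the full
descriptor table can be rebuilt offline. Rounding (4 decimals) happens only
at presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HARTREE_TO_EV",
    "FrontierOrbitals",
    "ReactivityDescriptors",
    "REFERENCE_FRONTIER_ORBITALS",
    "hartree_to_ev",
    "koopmans_descriptors",
    "build_reactivity_table",
    "read_orbitals_csv",
]

#: CODATA conversion factor, eV per Hartree.
HARTREE_TO_EV = 27.211386


@dataclass(frozen=True)
class FrontierOrbitals:
    """HOMO/LUMO energies (eV) plus optional pass-through properties."""

    compound: str
    e_homo: float
    e_lumo: float
    dipole: float | None = None         # Debye
    total_energy: float | None = None   # Hartree

    def __post_init__(self) -> None:
        if self.e_lumo < self.e_homo:
            warnings.warn(
                f"{self.compound}: E(LUMO) < E(HOMO); orbital ordering looks "
                "inverted",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    compound: str
    ionization_potential: float  # I, eV
    electron_affinity: float     # A, eV
    electronegativity: float     # chi, eV
    hardness: float              # eta, eV
    softness: float              # S, eV^-1
    electrophilicity: float      # omega, eV
    gap: float                   # dE, eV


#: Published B3LYP/6-31G(d) frontier-orbital inputs for the three most
#: promising flavonoids of the screen.
REFERENCE_FRONTIER_ORBITALS: dict[str, FrontierOrbitals] = {
    "egcg": FrontierOrbitals("egcg", e_homo=-5.4567, e_lumo=-0.9123,
                             dipole=4.1266, total_energy=-1675.696433),
    "chrysin": FrontierOrbitals("chrysin", e_homo=-5.9244, e_lumo=-1.4348,
                                dipole=3.6727, total_energy=-877.990789),
    "apigenin": FrontierOrbitals("apigenin", e_homo=-5.7215, e_lumo=-1.2744,
                                 dipole=2.4038, total_energy=-953.176777),
}


def hartree_to_ev(energy_hartree: float) -> float:
    """Convert an energy from Hartree to eV (CODATA factor)."""
    return energy_hartree * HARTREE_TO_EV


def koopmans_descriptors(orb: FrontierOrbitals) -> ReactivityDescriptors:
    """Derive the global reactivity descriptor set from HOMO/LUMO energies.

    Raises ``ZeroDivisionError`` with a clear message on a degenerate gap
    (eta = 0), where softness and electrophilicity are undefined.
    """
    ip = -orb.e_homo
    ea = -orb.e_lumo
    chi = (ip + ea) / 2.0
    eta = (ip - ea) / 2.0
    if eta == 0.0:
        raise ZeroDivisionError(
            f"{orb.compound}: degenerate HOMO-LUMO gap (eta = 0); softness "
            "and electrophilicity are undefined"
        )
    return ReactivityDescriptors(
        compound=orb.compound,
        ionization_potential=ip,
        electron_affinity=ea,
        electronegativity=chi,
        hardness=eta,
        softness=1.0 / (2.0 * eta),
        electrophilicity=chi * chi / (2.0 * eta),
        gap=orb.e_lumo - orb.e_homo,
    )


_ROW_ORDER = [
    ("Total Energy", "Hartree"),
    ("Dipole Moment", "Debye"),
    ("E(HOMO)", "eV"),
    ("E(LUMO)", "eV"),
    ("HOMO-LUMO Gap (dE)", "eV"),
    ("Ionization Potential (I)", "eV"),
    ("Electron Affinity (A)", "eV"),
    ("Electronegativity (chi)", "eV"),
    ("Chemical Hardness (eta)", "eV"),
    ("Chemical Softness (S)", "eV^-1"),
    ("Electrophilicity Index (omega)", "eV"),
]


def build_reactivity_table(orbitals: list[FrontierOrbitals]) -> pd.DataFrame:
    """Parameters-by-compounds table of inputs and derived descriptors.

    Rows are parameters (with a Unit column); one column per compound;
    values rounded to 4 decimals. Gap uses |dE| = I - A for presentation.
    """
    columns: dict[str, dict[str, float | None]] = {}
    for orb in orbitals:
        try:
            d = koopmans_descriptors(orb)
        except ZeroDivisionError as exc:
            raise ZeroDivisionError(f"{orb.compound}: {exc}") from exc
        columns[orb.compound] = {
            "Total Energy": orb.total_energy,
            "Dipole Moment": orb.dipole,
            "E(HOMO)": orb.e_homo,
            "E(LUMO)": orb.e_lumo,
            "HOMO-LUMO Gap (dE)": d.ionization_potential - d.electron_affinity,
            "Ionization Potential (I)": d.ionization_potential,
            "Electron Affinity (A)": d.electron_affinity,
            "Electronegativity (chi)": d.electronegativity,
            "Chemical Hardness (eta)": d.hardness,
            "Chemical Softness (S)": d.softness,
            "Electrophilicity Index (omega)": d.electrophilicity,
        }
    table = pd.DataFrame(
        {
            "Parameter": [name for name, _ in _ROW_ORDER],
            **{
                comp: [
                    None if vals[name] is None else round(vals[name], 4)
                    for name, _ in _ROW_ORDER
                ]
                for comp, vals in columns.items()
            },
            "Unit": [unit for _, unit in _ROW_ORDER],
        }
    )
    return table


def read_orbitals_csv(path) -> list[FrontierOrbitals]:
    """Read frontier orbitals from a key-value CSV.

    Expected columns: compound, e_homo_ev, e_lumo_ev, and optionally
    dipole_debye and total_energy_hartree. Full quantum-chemistry log
    parsing is deliberately out of scope; this documented CSV is the
    exchange format.
    """
    df = pd.read_csv(path)
    required = {"compound", "e_homo_ev", "e_lumo_ev"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orbitals CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            FrontierOrbitals(
                compound=str(row["compound"]),
                e_homo=float(row["e_homo_ev"]),
                e_lumo=float(row["e_lumo_ev"]),
                dipole=(float(row["dipole_debye"])
                        if "dipole_debye" in df.columns
                        and pd.notna(row["dipole_debye"]) else None),
                total_energy=(float(row["total_energy_hartree"])
                              if "total_energy_hartree" in df.columns
                              and pd.notna(row["total_energy_hartree"]) else None),
            )
        )
    return out
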