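"""Domain types for protein-ligand complexes, docked poses, and trajectories.

Coordinates are Angstrom throughout; no unit conversion happens at I/O
boundaries. PDB parsing is fixed-column per the wwPDB format; PDBQT parsing
understands the AutoDock Vina multi-pose output dialect (MODEL blocks with
``REMARK VINA RESULT:`` records). Extra PDBQT columns (partial charge,
AutoDock atom type) are retained losslessly but are not used downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "LigandMolecule",
    "DockedPose",
    "ComplexStructure",
    "Trajectory",
    "DockingConfig",
    "PDBParseError",
    "STANDARD_AMINO_ACIDS",
    "read_pdb",
    "write_pdb",
    "read_pdbqt_poses",
    "select_best_pose",
]

#: The 20 standard amino-acid residue names; HETATM records carrying any
#: other residue name (waters excluded) are treated as ligand atoms.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET
       PHE PRO SER THR TRP TYR VAL""".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3"})

POLAR_ELEMENTS = frozenset({"N", "O"})


class PDBParseError(ValueError):
    """Raised when a PDB/PDBQT record cannot be parsed; carries line number."""


@dataclass
class Atom:
    """A single atom with Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    aromatic_flag: bool = False
    partial_charge: float | None = None
    autodock_type: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element symbol must be non-empty")
        self.element = self.element.strip().capitalize()

    @property
    def is_polar(self) -> bool:
        """True for nitrogen and oxygen, the H-bond capable heavy atoms."""
        return self.element.upper() in POLAR_ELEMENTS

    @property
    def is_carbon(self) -> bool:
        return self.element.upper() == "C"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Residue:
    name: str
    chain: str
    number: int
    atoms: list[Atom]

    def __post_init__(self) -> None:
        self.name = self.name.upper()
        if not self.atoms:
            raise ValueError(f"residue {self.name}{self.number}: no atoms")

    @property
    def residue_id(self) -> str:
        """Table-style identifier, e.g. ``ASN458``."""
        return f"{self.name}{self.number}"


@dataclass
class ProteinStructure:
    residues: list[Residue]

    def __post_init__(self) -> None:
        keys = [(r.chain, r.number) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue number) pairs in protein")

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.iter_atoms()], dtype=float)


@dataclass
class LigandMolecule:
    name: str
    cid: int | None = None
    smiles: str | None = None
    atoms: list[Atom] | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.smiles is None and self.atoms is None and self.formula is None:
            raise ValueError(
                f"ligand {self.name!r}: need at least one of smiles/atoms/formula"
            )

    @property
    def has_coordinates(self) -> bool:
        return bool(self.atoms)

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            raise ValueError(f"ligand {self.name!r} has no 3D atoms")
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class DockedPose:
    """One docking pose: rank within its result set and Vina affinity.

    Affinities are kcal/mol; more negative is more favorable.
    """

    rank: int
    affinity: float
    ligand_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("pose rank must be >= 1")


@dataclass
class ComplexStructure:
    protein: ProteinStructure
    ligand: LigandMolecule

    def __post_init__(self) -> None:
        if not self.ligand.has_coordinates:
            raise ValueError("complex ligand must have at least one 3D atom")


@dataclass
class Trajectory:
    """Coordinate frames over a fixed topology (protein, optionally + ligand).

    ``frames`` has shape (n_frames, n_atoms, 3) with protein atoms first and
    ligand atoms (if any) appended, in topology order. Times are picoseconds.
    """

    topology: ProteinStructure
    frames: np.ndarray
    times: np.ndarray
    ligand: LigandMolecule | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n_atoms = self.topology.n_atoms + (
            len(self.ligand.atoms) if self.ligand and self.ligand.atoms else 0
        )
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_atoms, 3):
            raise ValueError(
                f"frames must have shape (n_frames, {n_atoms}, 3); "
                f"got {self.frames.shape}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_protein_atoms(self) -> int:
        return self.topology.n_atoms

    def frame_complex(self, i: int) -> ComplexStructure:
        """Materialize frame *i* as a ComplexStructure (requires a ligand)."""
        if self.ligand is None or not self.ligand.atoms:
            raise ValueError("trajectory has no ligand")
        coords = self.frames[i]
        n_prot = self.topology.n_atoms
        residues = []
        k = 0
        for res in self.topology.residues:
            atoms = []
            for a in res.atoms:
                atoms.append(
                    Atom(a.serial, a.name, a.element, coords[k],
                         aromatic_flag=a.aromatic_flag)
                )
                k += 1
            residues.append(Residue(res.name, res.chain, res.number, atoms))
        lig_atoms = [
            Atom(a.serial, a.name, a.element, coords[n_prot + j],
                 aromatic_flag=a.aromatic_flag)
            for j, a in enumerate(self.ligand.atoms)
        ]
        return ComplexStructure(
            ProteinStructure(residues),
            LigandMolecule(self.ligand.name, atoms=lig_atoms),
        )


@dataclass
class DockingConfig:
    """Search-box record for a Vina-style docking run.

    Defaults reproduce the study protocol: a cubic 22 A box centered on the
    apigenin site of the GLUT9 structure, exhaustiveness 32, 10 poses.
    """

    center: tuple[float, float, float] = (111.176, 105.825, 102.171)
    box_edge: float = 22.0
    exhaustiveness: int = 32
    n_poses: int = 10

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")


# ---------------------------------------------------------------------------
# PDB / PDBQT parsing (fixed columns per wwPDB spec)
# ---------------------------------------------------------------------------

def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def _element_from_record(line: str, name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem
    # fall back to the atom name: strip digits, take leading letter(s)
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "MG", "ZN"):
        return stripped[:2]
    return stripped[:1] if stripped else "X"


def _parse_atom_record(line: str, lineno: int) -> tuple[str, str, str, int, Atom]:
    """Return (record, resname, chain, resnum, Atom) for an ATOM/HETATM line."""
    record = line[:6].strip()
    altloc = line[16]
    name = line[12:16].strip()
    resname = line[17:20].strip().upper()
    chain = line[21].strip() or "A"
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed serial {line[6:11]!r}") from None
    try:
        resnum = int(line[22:26])
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed residue number {line[22:26]!r}"
        ) from None
    x = _parse_float(line[30:38], "x-coordinate", lineno)
    y = _parse_float(line[38:46], "y-coordinate", lineno)
    z = _parse_float(line[46:54], "z-coordinate", lineno)
    element = _element_from_record(line, name)
    # PDBQT: partial charge in cols 71-76, AutoDock type in 77-79
    charge = None
    adtype = None
    tail = line[66:].strip().split()
    if len(tail) >= 2 and tail[-1].isalpha():
        try:
            charge = float(tail[-2])
            adtype = tail[-1]
            element = adtype.rstrip("AaDd")[:2].capitalize() or adtype[:1]
            if adtype.upper() in ("A", "C", "CA", "CG0", "CG1"):
                element = "C"
            elif adtype.upper() in ("OA", "O"):
                element = "O"
            elif adtype.upper() in ("NA", "N"):
                element = "N"
            elif adtype.upper() in ("HD", "H", "HS"):
                element = "H"
            elif adtype.upper() in ("SA", "S"):
                element = "S"
        except ValueError:
            charge, adtype = None, None
    atom = Atom(serial, name, element, np.array([x, y, z]),
                partial_charge=charge, autodock_type=adtype)
    return record, resname, chain, resnum, atom, altloc


def _build_protein_and_ligand(
    records: list[tuple[str, str, str, int, Atom]],
    ligand_name: str = "LIG",
) -> tuple[ProteinStructure | None, LigandMolecule | None]:
    residues: dict[tuple[str, int], Residue] = {}
    order: list[tuple[str, int]] = []
    ligand_atoms: list[Atom] = []
    for record, resname, chain, resnum, atom in records:
        if resname in WATER_NAMES:
            continue
        is_ligand = record == "HETATM" and resname not in STANDARD_AMINO_ACIDS
        if is_ligand:
            ligand_atoms.append(atom)
            continue
        key = (chain, resnum)
        if key not in residues:
            residues[key] = Residue(resname, chain, resnum, [atom])
            order.append(key)
        else:
            residues[key].atoms.append(atom)
    protein = ProteinStructure([residues[k] for k in order]) if order else None
    ligand = (
        LigandMolecule(ligand_name, atoms=ligand_atoms) if ligand_atoms else None
    )
    return protein, ligand


def read_pdb(source: Union[str, TextIO]) -> Union[ComplexStructure, ProteinStructure, Trajectory]:
    """Parse a (multi-model) PDB text stream.

    Single-model input yields a :class:`ComplexStructure` when HETATM ligand
    atoms are present, else a bare :class:`ProteinStructure`. Input with
    multiple MODEL blocks yields a :class:`Trajectory` whose topology comes
    from the first model. AltLoc indicators other than ' ' or 'A' are skipped.
    """
    stream = _as_stream(source)
    models: list[list[tuple[str, str, str, int, Atom]]] = []
    current: list[tuple[str, str, str, int, Atom]] = []
    in_model = False
    saw_model = False
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
        elif rec in ("ATOM", "HETATM"):
            record, resname, chain, resnum, atom, altloc = _parse_atom_record(
                line, lineno
            )
            if altloc not in (" ", "A") or resname in WATER_NAMES:
                continue
            current.append((record, resname, chain, resnum, atom))
    if not saw_model:
        models = [current]
    elif in_model:  # unterminated final MODEL
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError("no atoms found in PDB input")

    protein, ligand = _build_protein_and_ligand(models[0])
    if len(models) == 1:
        if protein is None:
            raise PDBParseError("PDB input contains no protein atoms")
        if ligand is not None:
            return ComplexStructure(protein, ligand)
        return protein

    # multi-model -> trajectory; every model must have the same atom count.
    # Frames follow topology order: protein atoms first, ligand atoms last.
    n_atoms = len(models[0])
    is_lig = [
        rec == "HETATM" and resname not in STANDARD_AMINO_ACIDS
        for rec, resname, *_ in models[0]
    ]
    order_idx = [i for i, lig in enumerate(is_lig) if not lig] + [
        i for i, lig in enumerate(is_lig) if lig
    ]
    frames = np.empty((len(models), n_atoms, 3), dtype=float)
    for i, model in enumerate(models):
        if len(model) != n_atoms:
            raise PDBParseError(
                f"model {i + 1} has {len(model)} atoms; expected {n_atoms}"
            )
        frames[i] = [model[j][4].coords for j in order_idx]
    if protein is None:
        raise PDBParseError("trajectory input contains no protein atoms")
    times = np.arange(len(models), dtype=float)
    return Trajectory(protein, frames, times, ligand=ligand)


def _format_atom_line(record: str, atom: Atom, resname: str, chain: str,
                      resnum: int) -> str:
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.coords
    return (
        f"{record:<6s}{atom.serial:>5d} {name:<4s}{' '}{resname:<3s} {chain:1s}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element.upper():>2s}"
    )


def write_pdb(obj: Union[ComplexStructure, ProteinStructure, Trajectory],
              stream: TextIO) -> None:
    """Write a structure or trajectory as (multi-model) PDB text."""
    def write_single(protein: ProteinStructure,
                     ligand: LigandMolecule | None) -> None:
        for res in protein.residues:
            for atom in res.atoms:
                stream.write(
                    _format_atom_line("ATOM", atom, res.name, res.chain, res.number)
                    + "\n"
                )
        if ligand is not None and ligand.atoms:
            for atom in ligand.atoms:
                stream.write(
                    _format_atom_line("HETATM", atom, "LIG", "L", 1) + "\n"
                )

    if isinstance(obj, Trajectory):
        for i in range(obj.n_frames):
            stream.write(f"MODEL {i + 1:>8d}\n")
            coords = obj.frames[i]
            k = 0
            for res in obj.topology.residues:
                for atom in res.atoms:
                    moved = Atom(atom.serial, atom.name, atom.element, coords[k],
                                 aromatic_flag=atom.aromatic_flag)
                    stream.write(
                        _format_atom_line("ATOM", moved, res.name, res.chain,
                                          res.number) + "\n"
                    )
                    k += 1
            if obj.ligand is not None and obj.ligand.atoms:
                for j, atom in enumerate(obj.ligand.atoms):
                    moved = Atom(atom.serial, atom.name, atom.element,
                                 coords[obj.topology.n_atoms + j],
                                 aromatic_flag=atom.aromatic_flag)
                    stream.write(_format_atom_line("HETATM", moved, "LIG", "L", 1)
                                 + "\n")
            stream.write("ENDMDL\n")
    elif isinstance(obj, ComplexStructure):
        write_single(obj.protein, obj.ligand)
        stream.write("END\n")
    else:
        write_single(obj, None)
        stream.write("END\n")


def read_pdbqt_poses(source: Union[str, TextIO]) -> list[DockedPose]:
    """Parse AutoDock Vina multi-pose PDBQT output.

    Each MODEL block must carry a ``REMARK VINA RESULT:`` record; its first
    numeric field is the binding affinity in kcal/mol. Poses are ranked in
    order of appearance (Vina writes best-first).
    """
    stream = _as_stream(source)
    poses: list[DockedPose] = []
    affinity: float | None = None
    atoms: list[Atom] = []
    in_model = False
    model_index = 0

    def flush() -> None:
        nonlocal affinity, atoms
        if affinity is None:
            raise PDBParseError(
                f"model {model_index}: no 'REMARK VINA RESULT' record found"
            )
        poses.append(DockedPose(rank=len(poses) + 1, affinity=affinity,
                                ligand_atoms=atoms))
        affinity, atoms = None, []

    for lineno, line in enumerate(stream, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            model_index += 1
            affinity, atoms = None, []
        elif rec == "ENDMDL":
            in_model = False
            flush()
        elif line.startswith("REMARK VINA RESULT:"):
            fields = line.split(":", 1)[1].split()
            if not fields:
                raise PDBParseError(f"line {lineno}: empty VINA RESULT record")
            affinity = _parse_float(fields[0], "affinity", lineno)
        elif rec in ("ATOM", "HETATM") and in_model:
            *_, atom, altloc = _parse_atom_record(line, lineno)
            if altloc in (" ", "A"):
                atoms.append(atom)
    if in_model:  # unterminated final model
        flush()
    return poses


def select_best_pose(poses: Sequence[DockedPose]) -> DockedPose:
    """Return the pose with the lowest (most negative) binding affinity.

    Ties are broken by the lower rank, i.e. earlier appearance in the Vina
    output.
    """
    if not poses:
        raise ValueError("cannot select a pose from an empty list")
    return min(poses, key=lambda p: (p.affinity, p.rank))
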