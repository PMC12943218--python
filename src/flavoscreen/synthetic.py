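"""Seeded generators producing inputs with known ground truth.

These stand in for study artifacts that were never deposited: docked
complexes (toy complexes with contacts planted at exact distances),
MD trajectories (isotropic Gaussian jitter around a reference, optionally
with an intermittent planted hydrogen bond), and antioxidant assay readings
(triplicate 4PL dose-response points with Gaussian noise, plus Trolox
calibration standards). Every generator is a pure function of its arguments
and seed: reruns are bit-identical. Generators emit the same in-memory types
and file formats the analysis readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assays import DEFAULT_CONCENTRATIONS_UM, DoseResponseSeries, four_pl
from .interactions import InteractionCriteria, InteractionProfile
from .structures import (
    Atom,
    ComplexStructure,
    LigandMolecule,
    ProteinStructure,
    Residue,
    Trajectory,
)

__all__ = [
    "PlantSpec",
    "gen_planted_complex",
    "gen_jitter_trajectory",
    "gen_dose_response",
    "gen_trolox_standards",
]

_REGION_SPACING = 25.0  # A between planted-contact regions; >> any cutoff
_RING_RADIUS = 1.39     # A, aromatic C-C ring radius


@dataclass(frozen=True)
class PlantSpec:
    """Ground-truth recipe for a toy complex.

    Distances are per planted contact (scalar applied to all plants of the
    type, or one value per plant) and must not exceed the corresponding
    cutoff. Decoy residues are placed far beyond every cutoff.
    """

    n_hbonds: int = 0
    n_pistacks: int = 0
    n_hydrophobic: int = 0
    hbond_distances: float | Sequence[float] = 3.0
    pistack_distances: float | Sequence[float] = 5.0
    hydrophobic_distances: float | Sequence[float] = 3.5
    decoy_atoms: int = 0
    seed: int = 0


def _expand(dist: float | Sequence[float], n: int, label: str,
            cutoff: float, minimum: float) -> list[float]:
    values = [float(dist)] * n if np.isscalar(dist) else [float(v) for v in dist]
    if len(values) != n:
        raise ValueError(f"{label}: expected {n} distances, got {len(values)}")
    for v in values:
        if not (minimum <= v <= cutoff):
            raise ValueError(
                f"{label}: planted distance {v} outside [{minimum}, {cutoff}]"
            )
    return values


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _orthonormal_frame(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = _random_unit(rng)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(n, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def gen_planted_complex(
    spec: PlantSpec,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> tuple[ComplexStructure, InteractionProfile]:
    """Build a toy complex realizing exactly the requested contacts.

    Each planted contact lives in its own region (25 A apart, so regions
    cannot cross-talk at any default cutoff):

    * H-bond: an ASN side chain (CB, OD1, ND2) with a ligand oxygen at the
      target distance from OD1 (and safely outside the cutoff from ND2).
    * pi-stacking: a PHE ring (CG..CZ hexagon) with an aromatic ligand
      carbon on the ring axis so that all six ring atoms sit at exactly the
      target distance. If that distance also falls within the hydrophobic
      cutoff, the PHE is included in the expected hydrophobic list.
    * hydrophobic: a LEU CD1 carbon with a ligand carbon at the target
      distance.

    Decoy residues (alternating polar SER-OG / carbon ALA-CB / aromatic
    PHE-CZ single-atom residues) are placed ~1000 A away, far beyond every
    cutoff. Returns the complex and the exact expected profile.
    """
    rng = np.random.default_rng(spec.seed)
    hb_d = _expand(spec.hbond_distances, spec.n_hbonds, "hbond",
                   criteria.hbond_cutoff, 1.0)
    pi_d = _expand(spec.pistack_distances, spec.n_pistacks, "pistack",
                   criteria.pistack_cutoff, _RING_RADIUS + 0.1)
    hp_d = _expand(spec.hydrophobic_distances, spec.n_hydrophobic,
                   "hydrophobic", criteria.hydrophobic_cutoff, 1.0)

    residues: list[Residue] = []
    ligand_atoms: list[Atom] = []
    expected = InteractionProfile()
    serial = iter(range(1, 100000))
    resnum = 0

    def region_center(k: int) -> np.ndarray:
        return np.array([k * _REGION_SPACING, 0.0, 0.0]) + rng.normal(0, 0.5, 3)

    region = 0
    for d in hb_d:
        resnum += 1
        center = region_center(region)
        region += 1
        u = _random_unit(rng)
        cb = center
        od1 = cb + 1.4 * u
        nd2 = cb - 1.4 * u
        residues.append(Residue("ASN", "A", resnum, [
            Atom(next(serial), "CB", "C", cb),
            Atom(next(serial), "OD1", "O", od1),
            Atom(next(serial), "ND2", "N", nd2),
        ]))
        ligand_atoms.append(Atom(next(serial), "O1", "O", od1 + d * u))
        expected.hbond_residues.append(f"ASN{resnum}")

    pi_ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    for d in pi_d:
        resnum += 1
        center = region_center(region)
        region += 1
        u, v, normal = _orthonormal_frame(rng)
        atoms = []
        for i, name in enumerate(pi_ring_names):
            ang = np.pi / 3.0 * i
            pos = center + _RING_RADIUS * (np.cos(ang) * u + np.sin(ang) * v)
            atoms.append(Atom(next(serial), name, "C", pos))
        residues.append(Residue("PHE", "A", resnum, atoms))
        height = float(np.sqrt(d**2 - _RING_RADIUS**2))
        ligand_atoms.append(
            Atom(next(serial), "C1", "C", center + height * normal,
                 aromatic_flag=True)
        )
        expected.pistack_residues.append(f"PHE{resnum}")
        if d <= criteria.hydrophobic_cutoff:
            expected.hydrophobic_residues.append(f"PHE{resnum}")

    for d in hp_d:
        resnum += 1
        center = region_center(region)
        region += 1
        u = _random_unit(rng)
        residues.append(Residue("LEU", "A", resnum, [
            Atom(next(serial), "CD1", "C", center),
        ]))
        ligand_atoms.append(Atom(next(serial), "C2", "C", center + d * u))
        expected.hydrophobic_residues.append(f"LEU{resnum}")

    # decoys: single-atom residues ~1000 A off in +y, spaced apart
    decoy_kinds = [("SER", "OG", "O"), ("ALA", "CB", "C"), ("PHE", "CZ", "C")]
    for k in range(spec.decoy_atoms):
        resnum += 1
        resname, atname, element = decoy_kinds[k % 3]
        pos = np.array([k * _REGION_SPACING, 1000.0, 0.0]) + rng.normal(0, 1.0, 3)
        residues.append(Residue(resname, "A", resnum, [
            Atom(next(serial), atname, element, pos)
        ]))

    if not ligand_atoms:
        # keep the complex well-formed: one ligand carbon far from everything
        ligand_atoms.append(
            Atom(next(serial), "C99", "C", np.array([0.0, -1000.0, 0.0]))
        )

    # feasibility check: planted atoms must not collide across regions
    all_coords = np.array(
        [a.coords for r in residues for a in r.atoms]
        + [a.coords for a in ligand_atoms]
    )
    from scipy.spatial.distance import pdist

    if len(all_coords) > 1 and pdist(all_coords).min() < 0.5:
        raise ValueError("infeasible plant spec: overlapping atom placements")

    complex_ = ComplexStructure(
        ProteinStructure(residues),
        LigandMolecule("planted", atoms=ligand_atoms),
    )
    return complex_, expected


def gen_jitter_trajectory(
    reference: ProteinStructure,
    sigma: float,
    n_frames: int = 5000,
    ligand: LigandMolecule | None = None,
    planted_hbond_fraction: float | None = None,
    hbond_on_distance: float = 3.0,
    hbond_off_distance: float = 30.0,
    dt_ps: float = 20.0,
    seed: int = 0,
) -> Trajectory:
    """Isotropic Gaussian jitter around a reference structure.

    Every atom receives iid N(0, sigma^2) displacement per frame and axis.
    With ``planted_hbond_fraction`` f set (requires a ligand with a polar
    atom), the first polar ligand atom and the first polar protein atom are
    pinned: in exactly round(f * n_frames) frames (chosen by seeded
    permutation) they sit ``hbond_on_distance`` apart, otherwise
    ``hbond_off_distance`` apart, both jitter-free, so the per-frame H-bond
    count contributed by the pair is exact.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    prot_coords = reference.coordinates()
    lig_coords = (
        np.array([a.coords for a in ligand.atoms]) if ligand and ligand.atoms
        else np.zeros((0, 3))
    )
    base = np.vstack([prot_coords, lig_coords])
    frames = base[None, :, :] + rng.normal(0.0, sigma, (n_frames, *base.shape))

    if planted_hbond_fraction is not None:
        if not (0.0 <= planted_hbond_fraction <= 1.0):
            raise ValueError("planted_hbond_fraction must lie in [0, 1]")
        if ligand is None or not ligand.atoms:
            raise ValueError("hydrogen-bond planting requires a ligand")
        lig_polar = [j for j, a in enumerate(ligand.atoms) if a.is_polar]
        prot_polar = [
            i for i, (_, a) in enumerate(reference.iter_atoms()) if a.is_polar
        ]
        if not lig_polar or not prot_polar:
            raise ValueError("planting needs a polar atom on both sides")
        li = len(prot_coords) + lig_polar[0]
        pi = prot_polar[0]
        n_on = int(round(planted_hbond_fraction * n_frames))
        on_frames = rng.permutation(n_frames)[:n_on]
        direction = _random_unit(rng)
        anchor = base[pi]
        frames[:, pi, :] = anchor
        frames[:, li, :] = anchor + hbond_off_distance * direction
        frames[on_frames, li, :] = anchor + hbond_on_distance * direction

    times = dt_ps * np.arange(1, n_frames + 1, dtype=float)
    return Trajectory(reference, frames, times, ligand=ligand)


def gen_dose_response(
    params: tuple[float, float, float, float],
    noise_sd: float = 0.0,
    n_reps: int = 3,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    compound: str = "synthetic",
    seed: int = 0,
) -> DoseResponseSeries:
    """Triplicate 4PL dose-response readings with Gaussian noise.

    ``params`` is (a, d, c, b): zero-dose response, plateau, inflection
    concentration (uM), slope. The generating truth is recorded in the
    series metadata.
    """
    a, d, c, b = params
    if c <= 0:
        raise ValueError("inflection concentration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    clean = four_pl(conc, a, d, c, b)
    activities = clean[:, None] + rng.normal(0.0, noise_sd, (conc.size, n_reps))
    return DoseResponseSeries(
        compound=compound,
        concentrations=conc,
        activities=activities,
        truth={"a": a, "d": d, "c": c, "b": b, "noise_sd": noise_sd,
               "seed": seed},
    )


def gen_trolox_standards(
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    n: int = 6,
    conc_max: float = 1000.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(Trolox concentration, absorbance) calibration pairs on a line."""
    if n < 3:
        raise ValueError("need at least 3 calibration standards")
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.0, conc_max, n)
    absorb = slope * conc + intercept + rng.normal(0.0, noise_sd, n)
    return list(zip(conc.tolist(), absorb.tolist()))
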