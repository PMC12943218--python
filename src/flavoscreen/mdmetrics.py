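"""Trajectory analysis metrics: RMSD, RMSF, H-bond counts, and SASA.

* RMSD: least-squares Kabsch superposition of each frame's backbone onto
  the first frame, then root-mean-square deviation over the selection.
* RMSF: per-atom fluctuation about the mean structure after one alignment
  pass (align to frame 0, take the mean, re-align to the mean). Default
  selection is one C-alpha per residue.
* H-bond count series: per-frame count of polar ligand/protein atom pairs
  within the H-bond cutoff, delegated to the interaction profiler so both
  modules share one contact definition.
* SASA: Shrake-Rupley with golden-spiral point sampling on probe-expanded
  spheres (Bondi radii, 1.4 A water probe, 960 points by default).

Lengths are Angstrom internally; series offer nm conversion for
GROMACS-style plots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .interactions import InteractionCriteria, find_hbonds
from .structures import Atom, Trajectory

__all__ = [
    "MetricSeries",
    "DistributionSummary",
    "BONDI_RADII",
    "kabsch_superpose",
    "backbone_indices",
    "calpha_indices",
    "rmsd_series",
    "rmsf_profile",
    "hbond_count_series",
    "shrake_rupley_sasa",
    "summarize_distribution",
]

#: Bondi van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}


@dataclass
class MetricSeries:
    times: np.ndarray   # ps
    values: np.ndarray
    label: str
    units: str = "A"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")

    def to_nm(self) -> "MetricSeries":
        """Convert an Angstrom-valued series to nanometres."""
        if self.units == "A":
            return replace(self, values=self.values / 10.0, units="nm")
        if self.units == "A^2":
            return replace(self, values=self.values / 100.0, units="nm^2")
        return self


@dataclass(frozen=True)
class DistributionSummary:
    median: float
    q1: float
    q3: float
    min: float
    max: float
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3-vector, rmsd) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference``. The rotation
    is proper (det +1); reflections are corrected in the SVD step.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    cov = mob_c.T @ ref_c
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate (rank-deficient) point configuration")
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    moved = mob_c @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
    return rot, trans, rmsd


def _superpose_frames(frames: np.ndarray, reference: np.ndarray,
                      fit_idx: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit selection."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        rot, trans, _ = kabsch_superpose(frame[fit_idx], reference[fit_idx])
        out[i] = frame @ rot.T + trans
    return out


# ---------------------------------------------------------------------------
# Atom selections
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def backbone_indices(traj: Trajectory) -> np.ndarray:
    """Indices (into frame atoms) of protein backbone atoms N/CA/C/O.

    Topologies without backbone-named atoms (e.g. side-chain-only toy
    systems) fall back to every protein atom.
    """
    idx = [
        i for i, (_, atom) in enumerate(traj.topology.iter_atoms())
        if atom.name.upper() in _BACKBONE_NAMES
    ]
    if not idx:
        idx = list(range(traj.topology.n_atoms))
    return np.asarray(idx, dtype=int)


def calpha_indices(traj: Trajectory) -> np.ndarray:
    """One C-alpha index per residue (falls back to the first atom)."""
    idx = []
    offset = 0
    for res in traj.topology.residues:
        ca = next((k for k, a in enumerate(res.atoms)
                   if a.name.upper() == "CA"), 0)
        idx.append(offset + ca)
        offset += len(res.atoms)
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory,
                selection: Sequence[int] | None = None) -> MetricSeries:
    """Per-frame backbone RMSD (A) after superposition onto frame 0."""
    sel = np.asarray(
        selection if selection is not None else backbone_indices(traj),
        dtype=int,
    )
    if sel.size == 0:
        raise ValueError("empty atom selection for RMSD")
    ref = traj.frames[0][sel]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        *_, rmsd = kabsch_superpose(frame[sel], ref)
        values[i] = rmsd
    return MetricSeries(traj.times, values, "backbone RMSD", units="A")


def rmsf_profile(traj: Trajectory,
                 selection: Sequence[int] | None = None) -> np.ndarray:
    """Per-atom RMSF (A) about the mean structure, one alignment pass.

    Default selection is one C-alpha per residue. A single-frame trajectory
    yields all zeros (with a warning from numpy-free logic: there is no
    fluctuation to measure).
    """
    sel = np.asarray(
        selection if selection is not None else calpha_indices(traj),
        dtype=int,
    )
    if sel.size == 0:
        raise ValueError("empty atom selection for RMSF")
    if traj.n_frames < 2:
        import warnings

        warnings.warn("RMSF of a single-frame trajectory is identically zero",
                      stacklevel=2)
        return np.zeros(sel.size)
    # initial reference = raw coordinate mean (frame-order invariant),
    # then one refinement pass against the aligned mean
    aligned = _superpose_frames(traj.frames, traj.frames.mean(axis=0), sel)
    mean_structure = aligned.mean(axis=0)
    aligned = _superpose_frames(aligned, mean_structure, sel)
    mean_structure = aligned.mean(axis=0)
    disp = aligned[:, sel, :] - mean_structure[sel]
    return np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))


def hbond_count_series(
    traj: Trajectory,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> MetricSeries:
    """Per-frame count of intermolecular H-bond contacts (pair count)."""
    if traj.ligand is None or not traj.ligand.atoms:
        raise ValueError("trajectory has no ligand; cannot count "
                         "intermolecular hydrogen bonds")
    counts = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame_complex = traj.frame_complex(i)
        counts[i] = len(find_hbonds(frame_complex, criteria))
    return MetricSeries(traj.times, counts, "intermolecular H-bonds",
                        units="count")


def _golden_spiral_points(n: int) -> np.ndarray:
    """n roughly uniform unit-sphere points via the golden-angle spiral."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    atoms: Sequence[Atom],
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area (total, per-atom), A^2.

    Each atom's sphere is expanded by the probe radius and sampled with a
    golden-spiral point set; a point is accessible when it lies outside
    every other atom's expanded sphere.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not atoms:
        return 0.0, np.zeros(0)
    radii = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        key = atom.element.capitalize()
        if key not in BONDI_RADII:
            raise ValueError(f"no van der Waals radius for element {key!r}")
        radii[i] = BONDI_RADII[key] + probe
    coords = np.array([a.coords for a in atoms], dtype=float)
    sphere = _golden_spiral_points(n_points)
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        points = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            # neighbor prefilter: spheres must overlap to occlude
            if np.linalg.norm(coords[j] - coords[i]) >= radii[i] + radii[j]:
                continue
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        frac = accessible.mean()
        per_atom[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return float(per_atom.sum()), per_atom


def summarize_distribution(series: MetricSeries | np.ndarray) -> DistributionSummary:
    """Order statistics (linear-interpolation quartiles) of a metric series."""
    values = series.values if isinstance(series, MetricSeries) else np.asarray(
        series, dtype=float
    )
    if values.size == 0:
        raise ValueError("cannot summarize an empty series")
    q1, median, q3 = np.percentile(values, [25, 50, 75])
    return DistributionSummary(
        median=float(median),
        q1=float(q1),
        q3=float(q3),
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
    )
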