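"""Report orchestration: screening and assay report bundles.

Builds the study-style summary tables (affinity ranking, per-compound
interaction lists, descriptor/ADMET table, reactivity table, and the assay
IC50/FRAP table with an ANOVA/Tukey annex) from configured inputs, isolating
per-stage failures so one broken input never voids the whole report. Every
run emits a JSON manifest recording package/library versions and the exact
geometric and statistical parameters used.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admet import build_admet_table, mw_from_formula
from .assays import DoseResponseSeries, anova_tukey, fit_four_pl, frap_trolox_equivalents
from .compounds import (
    FLAVONOID_FIXTURES,
    REFERENCE_BINDING_AFFINITIES,
    load_ligand_fixture,
)
from .interactions import InteractionCriteria, profile_complex
from .reactivity import (
    REFERENCE_FRONTIER_ORBITALS,
    build_reactivity_table,
    read_orbitals_csv,
)
from .structures import ComplexStructure, read_pdb, read_pdbqt_poses, select_best_pose

__all__ = ["RunConfig", "run_screening_report", "run_assay_report"]

log = logging.getLogger("flavoscreen")


@dataclass
class RunConfig:
    """Inputs and parameters for one report run."""

    outdir: str = "flavoscreen_out"
    compounds: list[str] = field(
        default_factory=lambda: list(FLAVONOID_FIXTURES)
    )
    pose_files: dict[str, str] = field(default_factory=dict)     # compound -> PDBQT
    complex_files: dict[str, str] = field(default_factory=dict)  # compound -> PDB
    orbitals_csv: str | None = None
    doseresponse_csv: str | None = None
    frap_standards_csv: str | None = None
    frap_samples: dict[str, float] = field(default_factory=dict)
    frap_mass_factor: float = 1.0
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("schema_version", None)
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if crit:
            cfg.criteria = InteractionCriteria(**crit)
        for label, paths in (("pose", cfg.pose_files),
                             ("complex", cfg.complex_files)):
            for compound, p in paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"{label} file for {compound!r} not found: {p}"
                    )
        return cfg


def _manifest(config: RunConfig, stages: dict[str, dict]) -> dict:
    import rdkit
    import scipy

    return {
        "flavoscreen": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "rdkit": rdkit.__version__,
        },
        "parameters": {
            "hbond_cutoff": config.criteria.hbond_cutoff,
            "hydrophobic_cutoff": config.criteria.hydrophobic_cutoff,
            "pistack_cutoff": config.criteria.pistack_cutoff,
            "hbond_angle_min": config.criteria.hbond_angle_min,
            "hydrophobic_residues": sorted(config.criteria.hydrophobic_residues),
            "aromatic_residues": sorted(config.criteria.aromatic_residues),
            "seed": config.seed,
        },
        "stages": stages,
    }


def _run_stage(name: str, stages: dict, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
        stages[name] = {"status": "ok",
                        "seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s ok (%.3fs)", name, time.perf_counter() - t0)
        return result
    except Exception as exc:  # stage isolation is the contract
        stages[name] = {"status": "failed", "error": str(exc),
                        "seconds": round(time.perf_counter() - t0, 3)}
        log.warning("stage %s failed: %s", name, exc)
        return None


def _affinity_ranking(config: RunConfig) -> pd.DataFrame:
    rows = []
    for name in config.compounds:
        fixture = load_ligand_fixture(name)
        if name in config.pose_files:
            poses = read_pdbqt_poses(Path(config.pose_files[name]).read_text())
            affinity = select_best_pose(poses).affinity
        elif name in REFERENCE_BINDING_AFFINITIES:
            affinity = REFERENCE_BINDING_AFFINITIES[name]
        else:
            continue
        rows.append({
            "Compound": name,
            "PubChem CID": fixture.cid,
            "Molecular Formula": fixture.formula,
            "MW (g/mol)": mw_from_formula(fixture.formula),
            "Binding Affinity (kcal/mol)": affinity,
        })
    df = pd.DataFrame(rows).sort_values(
        "Binding Affinity (kcal/mol)", kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "Rank", np.arange(1, len(df) + 1))
    return df


def _interaction_table(config: RunConfig) -> pd.DataFrame:
    rows = []
    for name, path in config.complex_files.items():
        parsed = read_pdb(Path(path).read_text())
        if not isinstance(parsed, ComplexStructure):
            raise ValueError(f"{name}: {path} is not a protein-ligand complex")
        profile = profile_complex(parsed, config.criteria)
        rows.append({
            "Compound": name,
            "Hydrogen Bond Residues": ", ".join(profile.hbond_residues) or "-",
            "pi-Stacking Residues": ", ".join(profile.pistack_residues) or "-",
            "Hydrophobic Contacts": ", ".join(profile.hydrophobic_residues) or "-",
        })
    return pd.DataFrame(rows)


def run_screening_report(config: RunConfig) -> dict:
    """Emit the screening tables + manifest; per-stage failures isolated.

    Returns a dict with keys ``affinity``, ``interactions``, ``admet``,
    ``reactivity`` (DataFrames or None for failed/skipped stages) and
    ``manifest``. Tables are also written as CSV under ``config.outdir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    affinity = _run_stage("affinity_ranking", stages,
                          lambda: _affinity_ranking(config))
    if config.complex_files:
        interactions = _run_stage("interactions", stages,
                                  lambda: _interaction_table(config))
    else:
        interactions = None
        stages["interactions"] = {"status": "skipped",
                                  "reason": "no complex files configured"}
    admet = _run_stage(
        "admet", stages,
        lambda: build_admet_table(
            [load_ligand_fixture(n) for n in config.compounds]
        ),
    )
    if config.orbitals_csv:
        orbitals = read_orbitals_csv(config.orbitals_csv)
    else:
        orbitals = [
            REFERENCE_FRONTIER_ORBITALS[n] for n in config.compounds
            if n in REFERENCE_FRONTIER_ORBITALS
        ]
    if orbitals:
        reactivity = _run_stage("reactivity", stages,
                                lambda: build_reactivity_table(orbitals))
    else:
        reactivity = None
        stages["reactivity"] = {"status": "skipped",
                                "reason": "no orbital data for configured compounds"}

    for name, df in (("affinity_ranking", affinity),
                     ("interactions", interactions),
                     ("admet", admet), ("reactivity", reactivity)):
        if df is not None:
            df.to_csv(outdir / f"{name}.csv", index=False)
    manifest = _manifest(config, stages)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "affinity": affinity,
        "interactions": interactions,
        "admet": admet,
        "reactivity": reactivity,
        "manifest": manifest,
    }


def run_assay_report(config: RunConfig) -> dict:
    """Per-compound IC50 +/- SD and r^2, FRAP TE, and an ANOVA/Tukey annex.

    The dose-response CSV is long-form (compound, concentration_um,
    replicate, activity_percent). ANOVA compares compounds on their
    replicate activities at the highest shared concentration; it is skipped
    (and noted) with fewer than two compounds.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    annex: dict = {}
    rows = []

    if config.doseresponse_csv:
        df = pd.read_csv(config.doseresponse_csv)
        for compound in df["compound"].unique():
            def fit_one(compound=compound):
                series = DoseResponseSeries.from_frame(df, compound)
                fit = fit_four_pl(series)
                return {
                    "Compound": compound,
                    "IC50 (uM)": round(fit.ic50, 2),
                    "IC50 SD (uM)": round(fit.ic50_sd, 2),
                    "r^2": round(fit.r_squared, 4),
                }
            row = _run_stage(f"fit:{compound}", stages, fit_one)
            if row is not None:
                rows.append(row)

        groups = {}
        top = df["concentration_um"].max()
        for compound in df["compound"].unique():
            vals = df[(df["compound"] == compound)
                      & (df["concentration_um"] == top)]["activity_percent"]
            if len(vals) >= 2:
                groups[compound] = vals.to_numpy()
        if len(groups) >= 2:
            def run_anova():
                res = anova_tukey(groups)
                return {
                    "f_statistic": res.f_statistic,
                    "p_value": res.p_value,
                    "comparison": f"activities at {top} uM",
                    "pairwise": res.pairwise.to_dict(orient="records"),
                }
            annex["anova_tukey"] = _run_stage("anova_tukey", stages, run_anova)
        else:
            annex["anova_tukey"] = None
            stages["anova_tukey"] = {
                "status": "skipped",
                "reason": "ANOVA needs at least 2 compounds",
            }
    else:
        stages["dose_response"] = {"status": "skipped",
                                   "reason": "no dose-response CSV configured"}

    if config.frap_standards_csv and config.frap_samples:
        standards_df = pd.read_csv(config.frap_standards_csv)
        standards = list(
            zip(standards_df["concentration_um"], standards_df["absorbance"])
        )

        def run_frap():
            out = {}
            for compound, absorbance in config.frap_samples.items():
                res = frap_trolox_equivalents(
                    standards, absorbance, config.frap_mass_factor
                )
                out[compound] = round(res.te_per_gram, 1)
            return out

        frap = _run_stage("frap", stages, run_frap)
        if frap:
            for row in rows:
                row["FRAP (umol TE/g)"] = frap.get(row["Compound"], float("nan"))
            annex["frap"] = frap

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "assay_table.csv", index=False)
    manifest = _manifest(config, stages)
    (outdir / "assay_manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "assay_annex.json").write_text(json.dumps(annex, indent=2))
    return {"table": table, "annex": annex, "manifest": manifest}
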