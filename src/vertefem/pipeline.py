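"""End-to-end cohort orchestration.

Runs the full study design -- synthesize specimens, carve defects, augment,
compress to fracture, extract midsagittal stress profiles at each
specimen's 50%-defect fracture force, and assemble the cohort tables the
statistics layer consumes.  Cell results are cached as JSON so a completed
run directory is never recomputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import simulate_experimental_forces  # noqa: F401  (re-export)
from .exceptions import VertefemError
from .failure import LoadingProtocol, run_fracture
from .fem import FEModel, SolverOptions, build_mesh
from .geometry import DefectSpec, augment, enumerate_design, insert_defect
from .materials import PowerLawCoefficients, build_material_field
from .profiles import ProfileSpec, extract_profile
from .stats import condition_label, mixed_icc, paired_vs_intact, summarize, tag_region
from .synth import CohortSpec, SynthParams, synth_cohort

log = logging.getLogger("vertefem")


@dataclass
class RunConfig:
    """Full cohort run configuration with the study-design defaults:
    defect area fractions 20%/50% and augmentation moduli
    {50, 300, 1000, 2000, 2500} MPa; density-modulus coefficients default to
    the cohort means a = 7546, b = 2.0."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    fractions: tuple[float, ...] = (0.20, 0.50)
    moduli: tuple[float, ...] = (50.0, 300.0, 1000.0, 2000.0, 2500.0)
    coefficients: PowerLawCoefficients = field(
        default_factory=lambda: PowerLawCoefficients(a=7546.0, b=2.0))
    protocol: LoadingProtocol = field(default_factory=LoadingProtocol)
    defect_height_fraction: float = 0.5
    defect_shape: str = "elliptic_cylinder"
    solver: SolverOptions = field(default_factory=SolverOptions)
    outdir: Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            c = raw["cohort"]
            base = SynthParams(**c.pop("base_params", {}))
            kwargs["cohort"] = CohortSpec(base_params=base, **c)
        if "coefficients" in raw:
            kwargs["coefficients"] = PowerLawCoefficients(**raw["coefficients"])
        if "protocol" in raw:
            kwargs["protocol"] = LoadingProtocol(**raw["protocol"])
        if "solver" in raw:
            kwargs["solver"] = SolverOptions(**raw["solver"])
        for key in ("fractions", "moduli"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("defect_height_fraction", "defect_shape", "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "outdir" in kwargs:
            kwargs["outdir"] = Path(kwargs["outdir"])
        return cls(**kwargs)


@dataclass
class CohortOutputs:
    design: pd.DataFrame
    donors: pd.DataFrame
    results: pd.DataFrame  # one row per design cell: force, max stress, region
    paired_tests: pd.DataFrame | None
    mixed_model: object | None
    summary: str


def _cell_key(specimen: str, condition: str, fraction, modulus) -> str:
    parts = [specimen, condition]
    if fraction is not None and not (isinstance(fraction, float) and np.isnan(fraction)):
        parts.append(f"f{int(round(100 * fraction))}")
    if modulus is not None and not (isinstance(modulus, float) and np.isnan(modulus)):
        parts.append(f"E{int(round(modulus))}")
    return "_".join(parts)


class _CellCache:
    def __init__(self, outdir: Path | None):
        self.dir = outdir / "cells" if outdir is not None else None
        if self.dir is not None:
            self.dir.mkdir(parents=True, exist_ok=True)

    def get(self, key: str) -> dict | None:
        if self.dir is None:
            return None
        path = self.dir / f"{key}.json"
        return json.loads(path.read_text()) if path.exists() else None

    def put(self, key: str, row: dict) -> None:
        if self.dir is None:
            return
        (self.dir / f"{key}.json").write_text(json.dumps(row, indent=1, default=float))


def run_cohort(config: RunConfig) -> CohortOutputs:
    """Execute every design cell in dependency order and assemble outputs.

    Per specimen: intact and defect fracture runs come first, the
    50%-defect fracture force defines the profile load, then every
    condition's stress profile and the augmented fracture runs follow.  All
    conditions of one specimen share a single mesh (defects relabel voxels,
    they do not remove them), so the FE scatter pattern is built once.
    Deterministic for a fixed seed; cached cells are not recomputed.
    """
    cohort = replace(config.cohort, seed=config.seed)
    volumes, donors = synth_cohort(cohort)
    design = enumerate_design(cohort.n_vertebrae, config.fractions, config.moduli)
    cache = _CellCache(config.outdir)

    rows: list[dict] = []
    errors: list[str] = []
    for vol in volumes:
        spec_id = vol.metadata["specimen_id"]
        donor_id = vol.metadata["donor_id"]
        try:
            rows.extend(_run_specimen(vol, config, cache))
        except VertefemError as exc:
            log.error("specimen %s (donor %s) failed: %s", spec_id, donor_id, exc)
            errors.append(f"{spec_id}: {exc}")
            continue

    results = pd.DataFrame(rows)
    paired = mixed = None
    summary = ""
    if not results.empty:
        summary = summarize(results)
        if "max_stress_MPa" in results:
            try:
                paired = paired_vs_intact(results)
            except VertefemError as exc:
                log.warning("paired tests skipped: %s", exc)
            try:
                mixed = mixed_icc(results)
            except (VertefemError, np.linalg.LinAlgError) as exc:
                log.warning("mixed model skipped: %s", exc)

    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
        design.table.to_csv(config.outdir / "design.csv", index=False)
        donors.to_csv(config.outdir / "donors.csv", index=False)
        results.to_csv(config.outdir / "results.csv", index=False)
        if paired is not None:
            paired.to_csv(config.outdir / "paired_tests.csv", index=False)
        (config.outdir / "summary.txt").write_text(summary + "\n")

    if errors:
        raise VertefemError(f"{len(errors)} specimen(s) failed: " + "; ".join(errors))
    return CohortOutputs(design=design.table, donors=donors, results=results,
                         paired_tests=paired, mixed_model=mixed, summary=summary)


def _run_specimen(vol, config: RunConfig, cache: _CellCache) -> list[dict]:
    spec_id = vol.metadata["specimen_id"]
    donor_id = vol.metadata["donor_id"]
    mesh = build_mesh(vol)
    model = FEModel(mesh, options=config.solver)

    # condition volumes: intact, each defect fraction, each (fraction, modulus)
    cells: list[tuple[str, float, float, object]] = [("intact", np.nan, np.nan, vol)]
    defect_vols = {}
    for f in config.fractions:
        dv = insert_defect(vol, DefectSpec(fraction=f, shape=config.defect_shape,
                                           height_fraction=config.defect_height_fraction))
        defect_vols[f] = dv
        cells.append(("defect", f, np.nan, dv))
    for f in config.fractions:
        for m in config.moduli:
            cells.append(("augmented", f, m, augment(defect_vols[f], m)))

    # pass 1: fracture forces (intact + defects first, then augmented)
    rows = []
    for cond, f, m, cvol in cells:
        key = _cell_key(spec_id, cond, f, m)
        row = cache.get(key)
        if row is None:
            mats = build_material_field(cvol, config.coefficients,
                                        augmentation_modulus=None if np.isnan(m) else m)
            _, frac = run_fracture(mesh, mats, config.protocol, model=model)
            row = {"specimen": spec_id, "donor": donor_id, "condition": cond,
                   "fraction": None if np.isnan(f) else f,
                   "modulus_MPa": None if np.isnan(m) else m,
                   "fracture_force_N": frac.fracture_force,
                   "displacement_at_peak_mm": frac.displacement_at_peak,
                   "n_failed": frac.total_failed,
                   "terminated_by": frac.terminated_by}
        rows.append((key, row, cond, f, m, cvol))

    # reference load: this specimen's 50%-defect fracture force
    ref_rows = [r for _, r, c, f, _, _ in rows
                if c == "defect" and f is not None and np.isclose(f, max(config.fractions))]
    ref_load = ref_rows[0]["fracture_force_N"] if ref_rows else None

    # pass 2: stress profiles at the reference load
    out_rows = []
    for key, row, cond, f, m, cvol in rows:
        if ref_load is not None and "max_stress_MPa" not in row:
            mats = build_material_field(cvol, config.coefficients,
                                        augmentation_modulus=None if np.isnan(m) else m)
            prof = extract_profile(mesh, mats, ProfileSpec(load=ref_load), model=model)
            center = cvol.metadata.get("reference_level")
            if center is None:
                from .geometry import min_cross_section_level
                center = min_cross_section_level(cvol)
            center_mm = (center + 0.5) * cvol.spacing[2]
            row["max_stress_MPa"] = prof.max_stress
            row["region"] = tag_region(prof.z_mm, prof.stress, center_mm)
            row["reference_load_N"] = ref_load
        row["group"] = ("none" if row["fraction"] is None
                        else f"{row['fraction']:.0%}")
        row["condition_label"] = condition_label(cond, m if not np.isnan(m) else None)
        cache.put(key, row)
        out_rows.append(row)
    return out_rows
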