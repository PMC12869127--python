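"""End-to-end orchestration: preprocess -> broaden -> fit -> torsions -> report.

A single config (YAML or JSON) names the conformer library manifest, the
replicate target scans, the blank, and optional geometries; the pipeline
averages the scans, subtracts the baseline, resamples onto the fitting
grid, fits conformer abundances, and writes a JSON report plus an overlay
CSV (and per-conformer torsion CSVs when geometries are present).  Runs
with the same config are deterministic, so every reported abundance is
traceable to its HWHM / grid / constraint settings, which are echoed into
the report.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .fit import ConformerRecord, FitResult, fit_weights
from .geometry import backbone_map_from_pdb, backbone_torsions
from .preprocess import (
    MeasurementSeries,
    average_scans,
    mdeg_to_delta_epsilon,
    mg_ml_to_mol_per_L,
    subtract_baseline,
)
from .spectra import BroadeningSettings, Spectrum, resample

logger = logging.getLogger("ecdkit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and settings for one fit run.

    ``library_manifest`` is a CSV with columns ``id,energy,transitions_path``
    (optionally ``geometry_path,geometry_format``); relative paths resolve
    against the manifest location.
    """

    library_manifest: str
    target_scans: list[str]
    blank: str | None = None
    output_dir: str = "ecdkit-out"
    hwhm_nm: float = 10.0
    grid_start_nm: float = 185.0
    grid_end_nm: float = 320.0
    grid_step_nm: float = 0.5
    max_subset_size: int = 3
    weight_sum_cap: float = 1.0
    wavelength_shift_nm: float = 0.0
    concentration_mg_per_mL: float | None = None
    molar_mass_g_per_mol: float | None = None
    pathlength_cm: float = 0.1
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise PipelineError(f"config {path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in doc.items() if k in known}
        kwargs["extra"] = {k: v for k, v in doc.items() if k not in known}
        base = Path(path).parent
        cfg = cls(**kwargs)
        cfg.library_manifest = str((base / cfg.library_manifest))
        cfg.target_scans = [str(base / p) for p in cfg.target_scans]
        if cfg.blank:
            cfg.blank = str(base / cfg.blank)
        cfg.output_dir = str(base / cfg.output_dir)
        return cfg

    def broadening(self) -> BroadeningSettings:
        return BroadeningSettings(
            self.hwhm_nm, self.grid_start_nm, self.grid_end_nm, self.grid_step_nm
        )


def load_library_manifest(path: str | Path) -> list[ConformerRecord]:
    """Read a conformer library from a manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"library manifest not found: {path}")
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            transitions = fio.read_transitions_table(path.parent / row["transitions_path"])
            geometry = None
            geom_path = (row.get("geometry_path") or "").strip()
            if geom_path:
                geometry = fio.read_geometry(
                    path.parent / geom_path, (row.get("geometry_format") or "").strip() or None
                )
            records.append(
                ConformerRecord(
                    id=row["id"].strip(),
                    rel_energy_kcal_mol=float(row["energy"]),
                    transitions=transitions,
                    geometry=geometry,
                )
            )
    if not records:
        raise PipelineError(f"library manifest {path} lists no conformers")
    return records


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_fit_pipeline(config: PipelineConfig) -> FitResult:
    """Execute the full fit pipeline and write report files.

    Returns the :class:`FitResult`; the output directory receives
    ``report.json``, ``target_preprocessed.dat``, ``overlay.csv`` and, for
    conformers with geometries, ``torsions_<id>.csv``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = config.broadening()

    library = _stage("load_library")(load_library_manifest, config.library_manifest)
    logger.info("loaded %d conformers from %s", len(library), config.library_manifest)

    scans = [
        _stage("read_scans")(fio.read_spectrum_table, p, "millidegrees")
        for p in config.target_scans
    ]
    series = _stage("average_scans")(MeasurementSeries, scans)
    target = _stage("average_scans")(average_scans, series)
    if config.blank:
        blank = _stage("read_blank")(fio.read_spectrum_table, config.blank, "millidegrees")
        target = _stage("subtract_baseline")(subtract_baseline, target, blank)
    if config.concentration_mg_per_mL and config.molar_mass_g_per_mol:
        molarity = mg_ml_to_mol_per_L(config.concentration_mg_per_mL, config.molar_mass_g_per_mol)
        target = _stage("unit_conversion")(
            mdeg_to_delta_epsilon, target, molarity, config.pathlength_cm
        )

    # restrict the fitting grid to the measured range
    lo = max(settings.grid_start_nm, float(target.wavelengths_nm[0]))
    hi = min(settings.grid_end_nm, float(target.wavelengths_nm[-1]))
    if lo >= hi:
        raise PipelineError("stage 'resample' failed: target does not overlap the fitting grid")
    if (lo, hi) != (settings.grid_start_nm, settings.grid_end_nm):
        settings = BroadeningSettings(settings.hwhm_nm, lo, hi, settings.grid_step_nm)
    target = _stage("resample")(resample, target, settings.grid())
    fio.write_spectrum_table(target, out / "target_preprocessed.dat")

    result = _stage("fit_weights")(
        fit_weights,
        library,
        target,
        config.max_subset_size,
        config.weight_sum_cap,
        settings,
        config.wavelength_shift_nm,
    )
    result.settings["seed"] = config.seed
    fio.write_fit_report(result, out / "report.json")

    # overlay: target vs fitted combination on the fitting grid
    by_id = {rec.id: rec for rec in library}
    from .spectra import broaden  # local import to keep module init light

    fitted = np.zeros(settings.grid().size)
    for cid, w in zip(result.subset, result.weights):
        fitted += w * broaden(by_id[cid].transitions, settings).values
    with open(out / "overlay.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "target", "fitted"])
        for wl, tv, fv in zip(settings.grid(), target.values, fitted):
            writer.writerow([f"{wl:g}", f"{tv:.10g}", f"{fv:.10g}"])

    for cid in result.subset:
        rec = by_id[cid]
        if rec.geometry is None or rec.geometry.atom_names is None:
            continue
        try:
            table = backbone_torsions(rec.geometry, backbone_map_from_pdb(rec.geometry))
        except ValueError as exc:
            logger.warning("torsions for %s skipped: %s", cid, exc)
            continue
        with open(out / f"torsions_{cid}.csv", "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["linkage", "phi_deg", "psi_deg"])
            for k, (phi, psi) in enumerate(table.as_pairs(), start=1):
                writer.writerow([k, f"{phi:.1f}", f"{psi:.1f}"])

    logger.info(
        "fit: subset=%s weights=%s similarity=%.6f",
        result.subset,
        [round(float(w), 4) for w in result.weights],
        result.similarity if result.similarity is not None else float("nan"),
    )
    return result
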