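"""End-to-end simulate -> calibrate -> decompose -> quantify pipeline.

A single validated configuration drives the four stages; every artifact
lands in a run directory with a manifest recording the package version,
master seed, a config hash, and a checksum for each output file.  Stage
RNG streams are spawned deterministically from the master seed, so a rerun
with the same config and seed is bit-identical for the exact stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .calibration import DualEnergyCalibration
from .core import Grid, ScanProtocol, SensitivityMatrix
from .decomposition import DEFAULT_CONDITION_CAP, MaterialDecomposition
from .exceptions import ConfigurationError
from .nifti_io import write_dual_energy, write_labels, write_material_maps
from .quantification import compare_with_reference, quantify_rois, targeting_contrast
from .synthetic import (
    DEFAULT_ORGAN_CONCENTRATIONS_UG_ML,
    DEFAULT_VIAL_CONCENTRATIONS_UG_ML,
    MouseScenario,
    PhantomSpec,
    build_mouse,
    build_phantom,
    forward_project,
    vial_label_volume,
)

log = logging.getLogger("dectquant.pipeline")


class _Schema(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Schema):
    energy_low: float = 80.0
    energy_high: float = 140.0
    noise_sd: tuple[float, float] = (5.0, 5.0)
    pitch: float = 1.0
    mas: float = 250.0

    def protocol(self, voxel_size, seed: int) -> ScanProtocol:
        return ScanProtocol(
            energy_low=self.energy_low,
            energy_high=self.energy_high,
            voxel_size=tuple(voxel_size),
            noise_sd=self.noise_sd,
            seed=seed,
            pitch=self.pitch,
            mas=self.mas,
        )


class GridConfig(_Schema):
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def grid(self) -> Grid:
        return Grid(shape=tuple(self.shape), voxel_size=tuple(self.voxel_size))


class PhantomConfig(_Schema):
    body_radius: float = 30.0
    vial_radius: float = 4.0
    vial_concentrations_ug_ml: list[float] = Field(
        default_factory=lambda: list(DEFAULT_VIAL_CONCENTRATIONS_UG_ML)
    )
    background_material: Literal["pmma", "water"] = "pmma"
    grid: GridConfig = GridConfig(shape=(72, 72, 8), voxel_size=(1.0, 1.0, 0.625))

    def spec(self) -> PhantomSpec:
        return PhantomSpec(
            body_radius=self.body_radius,
            vial_radius=self.vial_radius,
            vial_concentrations=tuple(self.vial_concentrations_ug_ml),
            background_material=self.background_material,
        )


class MouseConfig(_Schema):
    organ_concentrations_ug_ml: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ORGAN_CONCENTRATIONS_UG_ML)
    )
    targeting_ratio: float = 2.0
    grid: GridConfig = GridConfig(shape=(80, 60, 72), voxel_size=(0.4, 0.4, 0.625))

    def scenario(self) -> MouseScenario:
        return MouseScenario(
            organ_concentrations=dict(self.organ_concentrations_ug_ml),
            targeting_ratio=self.targeting_ratio,
        )


class OptionsConfig(_Schema):
    clip_negative: bool = False
    weighted_fit: bool = False
    condition_cap: float = DEFAULT_CONDITION_CAP
    sensitivity: dict[str, float] = Field(
        default_factory=lambda: {"e_au_low": 22.0, "e_au_high": 27.0}
    )

    def true_sensitivity(self) -> SensitivityMatrix:
        return SensitivityMatrix.from_dict(self.sensitivity)


class PipelineConfig(_Schema):
    """Validated top-level configuration for :func:`run_pipeline`."""

    seed: int = 0
    protocol: ProtocolConfig = ProtocolConfig()
    phantom: PhantomConfig = PhantomConfig()
    mouse: MouseConfig = MouseConfig()
    options: OptionsConfig = OptionsConfig()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(d)
        except ValidationError as exc:
            locs = "; ".join(
                ".".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in exc.errors()
            )
            raise ConfigurationError(f"invalid pipeline config ({locs})") from exc

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Deterministic per-stage substream seeds (< 2^31) from the master."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute simulate -> calibrate -> decompose -> quantify; write a manifest.

    Returns the manifest dict (also written as ``manifest.json``).  The
    mouse leg runs twice, for the targeted and non-targeted probes, and
    reports the tumour uptake ratio alongside per-organ agreement with
    the scenario's ground-truth (reference) concentrations.
    """
    os.makedirs(outdir, exist_ok=True)
    master = config.seed if seed is None else int(seed)
    seeds = _stage_seeds(master)
    files: dict[str, str] = {}
    stages: list[str] = []

    def record(name: str, path: str) -> None:
        files[name] = path

    # --- stage 1: simulate -------------------------------------------------
    log.info("simulate: phantom %s, mouse %s", config.phantom.grid.shape, config.mouse.grid.shape)
    truth_sens = config.options.true_sensitivity()
    ph_grid = config.phantom.grid.grid()
    ph_spec = config.phantom.spec()
    ph_maps = build_phantom(ph_spec, ph_grid)
    ph_labels = vial_label_volume(ph_spec, ph_grid)
    ph_protocol = config.protocol.protocol(ph_grid.voxel_size, seeds[0])
    ph_image = forward_project(ph_maps, truth_sens, ph_protocol)

    mo_grid = config.mouse.grid.grid()
    scenario = config.mouse.scenario()
    results: dict[str, dict] = {}
    mouse_runs = {}
    for i, targeted in enumerate((False, True)):
        maps, geometry = build_mouse(scenario, mo_grid, targeted=targeted)
        protocol = config.protocol.protocol(mo_grid.voxel_size, seeds[1 + i])
        image = forward_project(maps, truth_sens, protocol)
        mouse_runs["targeted" if targeted else "nontargeted"] = (maps, geometry, image)

    record("phantom_image", write_dual_energy(ph_image, os.path.join(outdir, "phantom_hu.nii"), grid=ph_grid)[0])
    record("phantom_vial_labels", write_labels(ph_labels, os.path.join(outdir, "phantom_vials.nii"), ph_grid))
    for tag, (maps, geometry, image) in mouse_runs.items():
        record(f"mouse_{tag}_image", write_dual_energy(image, os.path.join(outdir, f"mouse_{tag}_hu.nii"), grid=mo_grid)[0])
        record(f"mouse_{tag}_labels", write_labels(geometry.label_map, os.path.join(outdir, f"mouse_{tag}_labels.nii"), mo_grid))
    stages.append("simulate")

    # --- stage 2: calibrate ------------------------------------------------
    cal = DualEnergyCalibration.from_image(
        ph_image, ph_labels, ph_spec.vial_concentrations
    ).fit(weighted=config.options.weighted_fit)
    log.info("calibrate: e_Au = (%.3f, %.3f), cond %.2f",
             cal.sensitivity.e_au_low, cal.sensitivity.e_au_high, cal.condition_number)
    fit_path = os.path.join(outdir, "fit.json")
    cal.to_json(fit_path)
    record("sensitivity_fit", fit_path)
    validation = cal.validate(list(ph_spec.vial_concentrations))
    val_path = os.path.join(outdir, "calibration_validation.csv")
    validation.to_csv(val_path, index=False)
    record("calibration_validation", val_path)
    stages.append("calibrate")

    # --- stage 3: decompose ------------------------------------------------
    decomp_results = {}
    for tag, (maps, geometry, image) in mouse_runs.items():
        res = MaterialDecomposition(
            image,
            cal.sensitivity,
            mask=geometry.body_mask,
            condition_cap=config.options.condition_cap,
        ).fit(clip_negative=config.options.clip_negative)
        decomp_results[tag] = (res, geometry, maps)
        map_paths = write_material_maps(res.maps, os.path.join(outdir, f"maps_{tag}"), mo_grid)
        for k, p in map_paths.items():
            record(f"maps_{tag}_{k}", p)
        results[f"decomposition_{tag}"] = {
            "negatives_fraction": res.negatives_fraction,
            "condition_number": res.solver_condition,
        }
    stages.append("decompose")

    # --- stage 4: quantify -------------------------------------------------
    reports = {}
    for tag, (res, geometry, truth) in decomp_results.items():
        stats = quantify_rois(res.maps, geometry)
        reference = quantify_rois(truth, geometry).set_index("organ")["mean_ug_ml"].to_dict()
        report = compare_with_reference(stats, reference)
        path = os.path.join(outdir, f"roi_report_{tag}.csv")
        report.to_csv(path)
        record(f"roi_report_{tag}", path)
        reports[tag] = report
        results[f"quantification_{tag}"] = {
            "correlation": report.correlation,
            "mean_bias_ug_ml": report.mean_bias_ug_ml,
            "mean_abs_relative_error": report.mean_abs_relative_error,
        }
    results["tumour_uptake_ratio"] = targeting_contrast(reports["targeted"], reports["nontargeted"])
    stages.append("quantify")

    manifest = {
        "package": "dectquant",
        "version": __version__,
        "seed": master,
        "stage_seeds": seeds[:3],
        "config_sha256": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": stages,
        "results": results,
        "files": {name: {"path": os.path.relpath(p, outdir), "sha256": _sha256(p)} for name, p in files.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
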