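"""End-to-end pipeline: generate -> estimate WET -> calibrate -> SPR -> sensitivity.

Every artifact written by the pipeline carries a provenance header (tool
version, config hash, seed, method tag) so a run can be reproduced from its
outputs alone; with a fixed config and seed the pipeline is idempotent and
its CSV outputs are byte-identical between runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationCurve, calibrate_from_sweep
from .images import hu_to_mu, write_matrix_fixture
from .phantoms import CouchSpec, HardeningModel, cylinder_phantom, ground_truth_wet, phantom_sweep, simulate_dect
from .sensitivity import sensitivity_table
from .spr import BetheSettings, SprImage, spr_image
from .surrogates import default_surrogates
from .tem import TEM_FUNCTIONS, WetProfile, estimate, estimate_profile, max_pairwise_deviation
from .images import AttenuationImage, HUImage

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run; round-trips through YAML."""

    seed: int = 0
    diameters: tuple[float, ...] = (75, 100, 125, 150, 175, 200, 225, 250, 275, 300, 325, 350, 375, 400)
    spacing_mm: float = 1.0
    noise_sigma_hu: float = 0.0
    with_couch: bool = False
    methods: tuple[str, ...] = ("tem-a", "tem-b1", "tem-b2")
    energy_mev: float = 100.0
    i_water_ev: float = 75.0
    bone_weight: float = 1.0
    wet_grid: tuple[float, ...] = (150, 200, 250, 300, 350, 400, 450)
    delta_mm: float | None = None  # None -> derive from the TEM spread on the sweep
    spr_diameter_mm: float = 200.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "diameters", tuple(float(d) for d in self.diameters))
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "wet_grid", tuple(float(w) for w in self.wet_grid))
        unknown = [m for m in self.methods if m not in TEM_FUNCTIONS]
        if unknown:
            raise ValueError(f"unknown methods in config: {unknown}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _provenance(config: RunConfig, method: str = "-") -> dict[str, str]:
    return {
        "wetspr_version": __version__,
        "config_hash": config.config_hash,
        "seed": str(config.seed),
        "method": method,
    }


def _write_csv(df: pd.DataFrame, path: Path, header: dict[str, str]) -> None:
    lines = [f"# {k}: {v}" for k, v in header.items()]
    path.write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def run_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Execute all stages in order and return the written artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    couch = CouchSpec() if config.with_couch else None

    # -- stage: generate-phantom -------------------------------------------
    try:
        sweep = phantom_sweep(
            config.diameters,
            seed=config.seed,
            spacing=config.spacing_mm,
            noise_sigma_hu=config.noise_sigma_hu,
            couch=couch,
        )
        tables = []
        for (spec, _, table), d in zip(sweep, config.diameters):
            t = table.copy()
            t.insert(0, "diameter_mm", d)
            tables.append(t)
        measurements = pd.concat(tables, ignore_index=True)
        path = outdir / "measurements.csv"
        _write_csv(measurements, path, _provenance(config))
        artifacts["measurements"] = path
        # image pair of the phantom used later for SPR maps
        spr_idx = int(np.argmin(np.abs(np.array(config.diameters) - config.spr_diameter_mm)))
        spr_spec, spr_de, _ = sweep[spr_idx]
        for tag, img in (("low", spr_de.low), ("high", spr_de.high)):
            p = outdir / f"phantom_{tag}.fixture"
            write_matrix_fixture(img, p, extra_header=_provenance(config))
            artifacts[f"phantom_{tag}"] = p
    except Exception as exc:
        raise PipelineError(f"stage generate-phantom failed: {exc}") from exc

    # -- stage: estimate-wet -----------------------------------------------
    try:
        rows = []
        profiles: dict[str, WetProfile] = {}
        mu_images = [hu_to_mu(de.low) for _, de, _ in sweep]
        for method in config.methods:
            profile = estimate_profile(method, mu_images)
            profiles[method] = profile
            for d, est in zip(config.diameters, profile.estimates):
                rows.append({"diameter_mm": d, "slice_index": est.slice_index, "method": method, "wet_mm": est.wet_mm})
        profile_df = pd.DataFrame(rows)
        path = outdir / "profiles.csv"
        _write_csv(profile_df, path, _provenance(config))
        artifacts["profiles"] = path
    except Exception as exc:
        raise PipelineError(f"stage estimate-wet failed: {exc}") from exc

    # -- stage: calibrate ---------------------------------------------------
    curves: dict[str, CalibrationCurve] = {}
    try:
        for method in config.methods:
            curve = calibrate_from_sweep(sweep, method, bone_weight=config.bone_weight, crop_couch=config.with_couch)
            curves[method] = curve
            path = outdir / f"curve_{method}.csv"
            curve.to_csv(path, header=_provenance(config, method))
            artifacts[f"curve_{method}"] = path
    except Exception as exc:
        raise PipelineError(f"stage calibrate failed: {exc}") from exc

    # -- stage: predict-spr -------------------------------------------------
    try:
        settings = BetheSettings(energy_mev=config.energy_mev, i_water_ev=config.i_water_ev)
        for method, curve in curves.items():
            wet = estimate(method, hu_to_mu(spr_de.low)).wet_mm
            spr = spr_image(spr_de, curve, wet, settings)
            p = outdir / f"spr_{method}.fixture"
            img = AttenuationImage(np.maximum(spr.pixels, 0.0), spr.spacing_x, spr.spacing_y, spr.slice_index)
            hdr = {**_provenance(config, method), **{k: str(v) for k, v in spr.provenance.items()}}
            hdr["quantity"] = "spr"
            write_matrix_fixture(img, p, extra_header=hdr)
            artifacts[f"spr_{method}"] = p
    except Exception as exc:
        raise PipelineError(f"stage predict-spr failed: {exc}") from exc

    # -- stage: sensitivity -------------------------------------------------
    try:
        if config.delta_mm is not None:
            delta = float(config.delta_mm)
        else:
            delta = max_pairwise_deviation([profiles[m] for m in config.methods])["max_mm"]
        table = sensitivity_table(
            default_surrogates(),
            config.wet_grid,
            delta,
            curves,
            settings,
            hardening=sweep[0][0].hardening,
        )
        path = outdir / "sensitivity.csv"
        hdr = _provenance(config)
        hdr["delta_mm"] = f"{delta:.17g}"
        _write_csv(table, path, hdr)
        artifacts["sensitivity"] = path
    except Exception as exc:
        raise PipelineError(f"stage sensitivity failed: {exc}") from exc

    return artifacts
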