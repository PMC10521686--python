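"""Configuration files, pose tables, field rasters and run manifests.

Interface conventions: lengths in mm, angles in degrees (the pose-table
convention), YAML configs with every key validated and unknown keys
rejected, pose tables as CSV with columns ``R_mm, theta_deg, phi_deg,
dx_mm, dy_mm`` (one row per fiber), fields written as 32-bit float TIFF
with an optional 8-bit max-normalized PNG preview.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cost import UFOVSpec
from .fields import EmitterSpec, FiberPose
from .optimize import DEFAULT_BOUNDS, OptimizationConfig

__all__ = [
    "DesignConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "read_pose_table",
    "write_pose_table",
    "write_manifest",
]

POSE_COLUMNS = ["R_mm", "theta_deg", "phi_deg", "dx_mm", "dy_mm"]


class ConfigError(ValueError):
    """Invalid design configuration; the message lists every offence."""


@dataclass
class DesignConfig:
    """A complete, serializable illumination-design specification."""

    ufov_x: float
    ufov_y: float
    n_fibers: int = 4
    half_angles: list[float] = field(default_factory=lambda: [6.0])
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BOUNDS.items()}
    )
    max_evaluations: int = 50_000
    mesh_tolerance: float = 1e-6
    step_tolerance: float = 1e-6
    ga_population: int = 120
    ga_generations: int = 80
    seed: int = 0
    cost: str = "combined"
    efficiency_mode: str = "inverted"
    cv_mode: str = "std"
    norm: str = "reference"
    term_normalization: str = "per_region"
    shift_mode: str = "translate"
    search_pitch: float = 0.1
    report_pitch: float = 0.05
    large_factor: float = 3.0
    output_dir: str = "."

    def validate(self) -> None:
        errors: list[str] = []
        if self.ufov_x <= 0:
            errors.append(f"ufov_x must be positive (got {self.ufov_x})")
        if self.ufov_y <= 0:
            errors.append(f"ufov_y must be positive (got {self.ufov_y})")
        if self.n_fibers < 1:
            errors.append(f"n_fibers must be >= 1 (got {self.n_fibers})")
        if len(self.half_angles) not in (1, self.n_fibers):
            errors.append(
                f"half_angles must list 1 shared or {self.n_fibers} per-fiber "
                f"values (got {len(self.half_angles)})"
            )
        for h in self.half_angles:
            if not 0.1 <= h < 90:
                errors.append(f"half_angle {h} outside [0.1, 90) degrees")
        unknown_bounds = set(self.bounds) - set(DEFAULT_BOUNDS)
        if unknown_bounds:
            errors.append(f"unknown bound keys: {sorted(unknown_bounds)}")
        for name, pair in self.bounds.items():
            if name in DEFAULT_BOUNDS:
                lo, hi = pair
                if lo >= hi:
                    errors.append(
                        f"bounds[{name!r}] has lower >= upper ({lo} >= {hi})"
                    )
        if self.max_evaluations < 1:
            errors.append("max_evaluations must be >= 1")
        for name in ("mesh_tolerance", "step_tolerance", "search_pitch",
                     "report_pitch"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.ga_population < 1 or self.ga_generations < 0:
            errors.append("ga_population must be >= 1 and ga_generations >= 0")
        if self.cost not in ("combined", "mean_max", "cv"):
            errors.append(f"cost must be combined|mean_max|cv (got {self.cost!r})")
        if self.efficiency_mode not in ("inverted", "literal"):
            errors.append("efficiency_mode must be inverted|literal")
        if self.cv_mode not in ("std", "var"):
            errors.append("cv_mode must be std|var")
        if self.norm not in ("reference", "field"):
            errors.append("norm must be reference|field")
        if self.term_normalization not in ("per_region", "common"):
            errors.append("term_normalization must be per_region|common")
        if self.shift_mode not in ("aim", "translate"):
            errors.append("shift_mode must be aim|translate")
        if self.large_factor <= 1:
            errors.append("large_factor must exceed 1")
        if errors:
            raise ConfigError("invalid config:\n  " + "\n  ".join(errors))

    # -- adapters ---------------------------------------------------------

    def ufov(self) -> UFOVSpec:
        return UFOVSpec(self.ufov_x, self.ufov_y, self.large_factor)

    def emitters(self) -> list[EmitterSpec]:
        angles = (
            self.half_angles
            if len(self.half_angles) == self.n_fibers
            else self.half_angles * self.n_fibers
        )
        return [EmitterSpec(h) for h in angles]

    def optimizer_config(self, seed: int | None = None) -> OptimizationConfig:
        return OptimizationConfig(
            n_fibers=self.n_fibers,
            bounds={k: tuple(v) for k, v in self.bounds.items()},
            max_evaluations=self.max_evaluations,
            mesh_tolerance=self.mesh_tolerance,
            step_tolerance=self.step_tolerance,
            ga_population=self.ga_population,
            ga_generations=self.ga_generations,
            seed=self.seed if seed is None else seed,
            cost=self.cost,
            efficiency_mode=self.efficiency_mode,
            cv_mode=self.cv_mode,
            norm=self.norm,
            term_normalization=self.term_normalization,
            shift_mode=self.shift_mode,
            search_pitch=self.search_pitch,
            report_pitch=self.report_pitch,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = {k: list(v) for k, v in d["bounds"].items()}
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> DesignConfig:
    """Read and validate a YAML design config.

    A minimal file needs only ``ufov_x`` and ``ufov_y``; every other key
    takes its documented default.  Unknown keys are an error (all offending
    keys are listed at once).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    known = set(DesignConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            "invalid config:\n  unknown keys: " + ", ".join(sorted(unknown))
        )
    missing = {k for k in ("ufov_x", "ufov_y") if k not in raw}
    if missing:
        raise ConfigError(
            "invalid config:\n  missing required keys: " + ", ".join(sorted(missing))
        )
    if "bounds" in raw:
        raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
    cfg = DesignConfig(**raw)
    cfg.validate()
    return cfg


def save_config(config: DesignConfig, path) -> None:
    config.validate()
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_pose_table(path) -> list[FiberPose]:
    """Read a fiber pose table (CSV, one row per fiber)."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose table {path} is missing columns {missing}")
    if df.empty:
        raise ValueError(f"pose table {path} contains no rows")
    sub = df[POSE_COLUMNS]
    if not all(np.issubdtype(d, np.number) for d in sub.dtypes):
        bad = [c for c, d in sub.dtypes.items() if not np.issubdtype(d, np.number)]
        raise ValueError(f"pose table {path} has non-numeric cells in {bad}")
    return [
        FiberPose(r.R_mm, r.theta_deg, r.phi_deg, r.dx_mm, r.dy_mm)
        for r in sub.itertuples()
    ]


def write_pose_table(poses: list[FiberPose], path) -> None:
    df = pd.DataFrame(
        [[p.R, p.theta, p.phi, p.dx, p.dy] for p in poses], columns=POSE_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(path, config: DesignConfig | None = None, **entries) -> None:
    """JSON run manifest: config hash, seed, versions, extra entries."""
    manifest = {
        "package": "lumiplan",
        "numpy": np.__version__,
    }
    from . import __version__

    manifest["version"] = __version__
    if config is not None:
        manifest["config_hash"] = config.content_hash()
        manifest["config"] = config.to_dict()
    manifest.update(entries)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
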