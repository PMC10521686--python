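"""Model/Results interface for illumination design.

:class:`IlluminationDesign` bundles the design problem — emitters, target
uniform field of view, bounds, budgets — the way a statistical model
bundles data and specification; ``fit()`` runs the genetic-seeded pattern
search and returns a :class:`DesignResult` carrying the optimized poses,
the cost trace, diagnostics and rendering/plotting helpers.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cost import CostEvaluator, UFOVSpec
from .fields import EmitterSpec, IrradianceField, PlaneGrid, irradiance_net
from .optimize import (
    OptimizationConfig,
    OptimizationResult,
    RepeatabilityStudy,
    optimize_illumination,
    repeatability_study,
)

__all__ = ["IlluminationDesign", "DesignResult"]


class IlluminationDesign:
    """A fiber-illumination design problem ready to be optimized.

    Parameters
    ----------
    emitters
        One :class:`EmitterSpec` per fiber (or a single shared spec).
    ufov
        Target uniform field of view.
    config
        Optimizer settings; defaults to :class:`OptimizationConfig`.
    """

    def __init__(
        self,
        emitters: list[EmitterSpec] | EmitterSpec,
        ufov: UFOVSpec,
        config: OptimizationConfig | None = None,
    ) -> None:
        self.config = config or OptimizationConfig()
        if isinstance(emitters, EmitterSpec):
            emitters = [emitters] * self.config.n_fibers
        if len(emitters) != self.config.n_fibers:
            raise ValueError(
                f"{len(emitters)} emitters for n_fibers={self.config.n_fibers}"
            )
        self.emitters = list(emitters)
        self.ufov = ufov

    @classmethod
    def from_config(cls, config) -> "IlluminationDesign":
        """Build from a :class:`lumiplan.io.DesignConfig`."""
        return cls(config.emitters(), config.ufov(), config.optimizer_config())

    def fit(self, seed: int | None = None) -> "DesignResult":
        """Run the global optimization; returns the result object."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        raw = optimize_illumination(self.emitters, self.ufov, None, cfg)
        return DesignResult(self, raw, cfg)

    def repeatability(self, n_runs: int = 5) -> RepeatabilityStudy:
        return repeatability_study(
            self.emitters, self.ufov, None, self.config, n_runs=n_runs
        )


class DesignResult:
    """Optimized design: poses, diagnostics, rendering and summaries."""

    def __init__(
        self,
        model: IlluminationDesign,
        raw: OptimizationResult,
        config: OptimizationConfig,
    ) -> None:
        self.model = model
        self.raw = raw
        self.config = config

    # -- estimates --------------------------------------------------------

    @property
    def poses(self):
        return self.raw.poses

    @property
    def final_cost(self) -> float:
        return self.raw.final_cost

    def poses_frame(self) -> pd.DataFrame:
        """Pose table in the standard column layout, one row per fiber."""
        return pd.DataFrame(
            self.raw.poses_array(),
            columns=["R_mm", "theta_deg", "phi_deg", "dx_mm", "dy_mm"],
            index=[f"fiber_{i + 1}" for i in range(len(self.poses))],
        )

    # -- rendering --------------------------------------------------------

    def field(
        self,
        pitch: float | None = None,
        extent: tuple[float, float] | None = None,
    ) -> IrradianceField:
        """Render the net field (default: the 3x large region, report pitch)."""
        pitch = pitch or self.config.report_pitch
        if extent is None:
            grid = self.model.ufov.grid(pitch, large=True)
        else:
            grid = PlaneGrid(extent[0], extent[1], pitch)
        return irradiance_net(
            self.poses, self.model.emitters, grid,
            shift_mode=self.config.shift_mode,
        )

    def mean_ufov_irradiance(self, pitch: float | None = None) -> float:
        fld = self.field(pitch)
        mask = fld.grid.rect_mask(self.model.ufov.ufov_x, self.model.ufov.ufov_y)
        return float(fld.values[mask].mean())

    def cost_terms(self) -> dict[str, float]:
        """Decompose the final cost into its mean-max and efficiency parts."""
        ev = CostEvaluator(
            self.model.emitters,
            self.model.ufov,
            pixel_pitch=self.config.search_pitch,
            cost="combined",
            efficiency_mode=self.config.efficiency_mode,
            norm=self.config.norm,
            term_normalization=self.config.term_normalization,
            shift_mode=self.config.shift_mode,
        )
        vals, mean_large = ev._accumulate(self.raw.x)
        inside = vals[ev._ufov_idx]
        t1 = 1.0 - inside.mean() / inside.max()
        t2 = mean_large / inside.mean()
        if self.config.efficiency_mode == "literal":
            t2 = 1.0 / t2
        return {"mean_max": float(t1), "efficiency": float(t2)}

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        terms = self.cost_terms() if self.config.cost == "combined" else None
        u = self.model.ufov
        lines = [
            "Illumination design result",
            "==========================",
            f"uFOV             : {u.ufov_x:g} x {u.ufov_y:g} mm",
            f"fibers           : {len(self.poses)}",
            f"half-angles (deg): "
            + ", ".join(f"{e.half_angle:g}" for e in self.model.emitters),
            f"cost ({self.config.cost:>8s})  : {self.final_cost:.6f}",
        ]
        if terms is not None:
            lines.append(
                f"  mean-max term  : {terms['mean_max']:.6f}\n"
                f"  efficiency term: {terms['efficiency']:.6f}"
            )
        lines += [
            f"evaluations      : {self.raw.n_evaluations}",
            f"termination      : {self.raw.termination_reason}",
            f"seed             : {self.raw.seed}",
            "",
            self.poses_frame().round(3).to_string(),
        ]
        return "\n".join(lines)

    def plot_field(self, ax=None, pitch: float | None = None):
        """Image of the net field with the uFOV box drawn (matplotlib)."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Rectangle

        fld = self.field(pitch)
        if ax is None:
            _, ax = plt.subplots()
        g = fld.grid
        extent = (-g.extent_x / 2, g.extent_x / 2, -g.extent_y / 2, g.extent_y / 2)
        im = ax.imshow(
            fld.values / fld.values.max(), origin="lower", extent=extent,
            cmap="inferno",
        )
        u = self.model.ufov
        ax.add_patch(
            Rectangle(
                (-u.ufov_x / 2, -u.ufov_y / 2), u.ufov_x, u.ufov_y,
                fill=False, edgecolor="white", linewidth=1.2,
            )
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.figure.colorbar(im, ax=ax, label="relative irradiance")
        return ax

    def save(self, out_dir) -> None:
        """Write poses CSV, cost-trace CSV, field TIFF/PNG and manifest."""
        from .io import write_manifest, write_pose_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pose_table(self.poses, out / "poses.csv")
        pd.DataFrame(
            self.raw.cost_trace, columns=["evaluation", "best_cost"]
        ).to_csv(out / "cost_trace.csv", index=False)
        fld = self.field()
        fld.save_tiff(out / "field.tif")
        fld.save_png_preview(out / "field_preview.png")
        write_manifest(
            out / "manifest.json",
            seed=self.raw.seed,
            termination=self.raw.termination_reason,
            evaluations=self.raw.n_evaluations,
            final_cost=self.final_cost,
        )
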