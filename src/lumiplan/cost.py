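"""Cost functions scoring illumination fields for uniformity and efficiency.

The design cost is the scalarized sum of two ratio terms evaluated on the
net field:

* a mean-max term, ``1 - mean(E)/max(E)`` within the uniform field of view
  (uFOV), which is zero only for a perfectly flat field; and
* an efficiency term comparing illumination over a concentric region three
  times the uFOV in each dimension with illumination inside the uFOV,
  penalizing light that spills outside the target.

A coefficient-of-variation cost is provided as the conventional baseline.
All terms are ratios and therefore invariant to a global positive rescale
of the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import EmitterSpec, FiberPose, IrradianceField, PlaneGrid, _single_values

__all__ = [
    "UFOVSpec",
    "mean_max_term",
    "efficiency_term",
    "combined_cost",
    "cv_cost",
    "CostEvaluator",
]


@dataclass(frozen=True)
class UFOVSpec:
    """Rectangular uniform field of view, centered at the origin (mm).

    The confinement penalty is computed against the concentric "large"
    region of size (large_factor * ufov_x) x (large_factor * ufov_y).
    """

    ufov_x: float
    ufov_y: float
    large_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.ufov_x <= 0 or self.ufov_y <= 0:
            raise ValueError("uFOV dimensions must be positive")
        if self.large_factor <= 1:
            raise ValueError("large_factor must exceed 1")

    @property
    def large_x(self) -> float:
        return self.large_factor * self.ufov_x

    @property
    def large_y(self) -> float:
        return self.large_factor * self.ufov_y

    def grid(self, pixel_pitch: float, large: bool = False) -> PlaneGrid:
        """A grid covering the uFOV (or the concentric large region)."""
        if large:
            return PlaneGrid(self.large_x, self.large_y, pixel_pitch)
        return PlaneGrid(self.ufov_x, self.ufov_y, pixel_pitch)


def mean_max_term(field: IrradianceField, ufov: UFOVSpec) -> float:
    """``1 - mean/max`` of the field within the uFOV; 0 iff perfectly flat."""
    mask = field.grid.rect_mask(ufov.ufov_x, ufov.ufov_y)
    vals = field.values[mask]
    vmax = vals.max()
    if vmax == 0.0:
        raise ValueError("field is identically zero on the uFOV")
    return float(1.0 - vals.mean() / vmax)


def efficiency_term(
    field_ufov: IrradianceField,
    field_large: IrradianceField,
    ufov: UFOVSpec,
    mode: str = "inverted",
) -> float:
    """Confinement penalty relating light inside and outside the uFOV.

    ``field_large`` must cover the concentric large region at the same
    pitch; ``field_ufov`` is the field restricted to the uFOV.  In the
    default "inverted" orientation the term is

        mean(E over large region) / mean(E within uFOV)

    so that minimization rewards confining light to the uFOV (1/large_factor^2
    for a field that is uniform inside the uFOV and zero outside, 1.0 when
    light is spread uniformly over the whole large region).  ``mode="literal"``
    returns the reciprocal orientation.
    """
    mean_ufov = field_ufov.values.mean()
    mean_large = field_large.values.mean()
    if mean_ufov == 0.0 or mean_large == 0.0:
        raise ValueError("region mean is zero")
    if mode == "inverted":
        return float(mean_large / mean_ufov)
    if mode == "literal":
        return float(mean_ufov / mean_large)
    raise ValueError(f"unknown efficiency mode {mode!r}")


def cv_cost(field: IrradianceField, ufov: UFOVSpec, mode: str = "std") -> float:
    """Coefficient of variation of the field within the uFOV.

    ``mode="std"`` (default) is the standard definition std/mean using
    population moments; ``mode="var"`` returns variance/mean.
    """
    mask = field.grid.rect_mask(ufov.ufov_x, ufov.ufov_y)
    vals = field.values[mask]
    mean = vals.mean()
    if mean == 0.0:
        raise ValueError("field mean is zero on the uFOV")
    if mode == "std":
        return float(vals.std() / mean)
    if mode == "var":
        return float(vals.var() / mean)
    raise ValueError(f"unknown cv mode {mode!r}")


def combined_cost(
    poses: list[FiberPose],
    emitters: list[EmitterSpec] | EmitterSpec,
    grid_spec: PlaneGrid | float,
    ufov: UFOVSpec,
    efficiency_mode: str = "inverted",
) -> float:
    """Mean-max plus efficiency cost of a candidate design.

    The net field is evaluated over the concentric large region with its
    per-source normalization taken over the uFOV, then both terms are
    formed from that field.  ``grid_spec`` may be a grid covering the large
    region or simply a pixel pitch.
    """
    if isinstance(emitters, EmitterSpec):
        emitters = [emitters] * len(poses)
    pitch = grid_spec.pixel_pitch if isinstance(grid_spec, PlaneGrid) else grid_spec
    ev = CostEvaluator(emitters, ufov, pitch, cost="combined",
                       efficiency_mode=efficiency_mode)
    return ev.cost_of_poses(poses)


class CostEvaluator:
    """Vectorized design-cost evaluation reused across optimizer calls.

    Grid geometry, region masks and the per-emitter reference means are
    precomputed once; each call evaluates the net field for a flat pose
    parameter vector ``[R, theta, phi, dx, dy] * n_fibers`` (degrees, mm)
    and returns the selected scalar cost.  The net field uses the same
    normalization choices as :func:`lumiplan.fields.irradiance_net`, with
    the normalization region fixed to the uFOV (the region the field is
    scored over during design optimization).
    """

    def __init__(
        self,
        emitters: list[EmitterSpec],
        ufov: UFOVSpec,
        pixel_pitch: float = 0.1,
        cost: str = "combined",
        efficiency_mode: str = "inverted",
        cv_mode: str = "std",
        ref_R: float = 5.0,
        norm: str = "reference",
        term_normalization: str = "per_region",
        shift_mode: str = "translate",
    ) -> None:
        if cost not in ("combined", "mean_max", "cv"):
            raise ValueError(f"unknown cost {cost!r}")
        if norm not in ("reference", "field"):
            raise ValueError(f"unknown norm {norm!r}")
        if term_normalization not in ("per_region", "common"):
            raise ValueError(f"unknown term_normalization {term_normalization!r}")
        if shift_mode not in ("aim", "translate"):
            raise ValueError(f"unknown shift_mode {shift_mode!r}")
        if efficiency_mode not in ("inverted", "literal"):
            raise ValueError(f"unknown efficiency mode {efficiency_mode!r}")
        self.norm = norm
        self.term_normalization = term_normalization
        self.shift_mode = shift_mode
        self.emitters = list(emitters)
        self.ufov = ufov
        self.cost = cost
        self.efficiency_mode = efficiency_mode
        self.cv_mode = cv_mode
        # combined / mean_max need the large region for the efficiency term;
        # the CV baseline only looks inside the uFOV.
        large = cost == "combined"
        self.grid = ufov.grid(pixel_pitch, large=large)
        X, Y = self.grid.meshgrid()
        mask = self.grid.rect_mask(ufov.ufov_x, ufov.ufov_y)
        self._x = X.ravel()
        self._y = Y.ravel()
        self._ufov_idx = np.flatnonzero(mask.ravel())
        self._ms = np.array([e.m for e in self.emitters])
        # mean of the on-axis short-distance reference field, one constant
        # per emitter, over the uFOV and over the full evaluation grid: the
        # uFOV-region field and the large-region field are each normalized
        # against the reference mean taken on their own region
        ref_pose = FiberPose(ref_R, 0.0, 0.0)
        self._ref_means = np.array(
            [
                _single_values(ref_pose, e, self._x[self._ufov_idx],
                               self._y[self._ufov_idx]).mean()
                for e in self.emitters
            ]
        )
        self._ref_means_grid = np.array(
            [
                _single_values(ref_pose, e, self._x, self._y).mean()
                for e in self.emitters
            ]
        )
        if self.term_normalization == "common":
            self._ref_means_grid = self._ref_means.copy()
        self.n_params = 5 * len(self.emitters)

    def _accumulate(self, params: np.ndarray) -> tuple[np.ndarray, float]:
        """(uFOV-normalized net field over the grid, grid mean of the
        grid-normalized net field)."""
        params = np.asarray(params, dtype=float)
        if params.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} parameters, got {params.size}"
            )
        p = params.reshape(-1, 5)
        R, theta, phi = p[:, 0], np.radians(p[:, 1]), np.radians(p[:, 2])
        sin_t = np.sin(theta)
        Sx = R * sin_t * np.cos(phi)
        Sy = R * sin_t * np.sin(phi)
        Sz = R * np.cos(theta)
        total = np.zeros_like(self._x)
        mean_grid_norm = 0.0
        for n in range(len(self.emitters)):
            if self.shift_mode == "aim":
                bx = p[n, 3] - Sx[n]
                by = p[n, 4] - Sy[n]
                bz = -Sz[n]
                bn = np.sqrt(bx * bx + by * by + bz * bz)
                vx = self._x - Sx[n]
                vy = self._y - Sy[n]
                d2 = vx * vx + vy * vy + Sz[n] * Sz[n]
                cospsi = (vx * bx + vy * by + Sz[n] * Sz[n]) / (bn * np.sqrt(d2))
            else:
                vx = Sx[n] - (self._x - p[n, 3])
                vy = Sy[n] - (self._y - p[n, 4])
                d2 = vx * vx + vy * vy + Sz[n] * Sz[n]
                cospsi = (vx * Sx[n] + vy * Sy[n] + Sz[n] * Sz[n]) / (
                    R[n] * np.sqrt(d2)
                )
            vals = np.zeros_like(d2)
            front = cospsi > 0.0
            vals[front] = np.exp(self._ms[n] * np.log(cospsi[front])) / d2[front]
            if self.norm == "reference":
                scale = 1.0 / self._ref_means[n]
            else:
                mean_n = vals[self._ufov_idx].mean()
                if mean_n == 0.0:
                    raise ValueError(
                        "a source contributes zero mean irradiance on the uFOV"
                    )
                scale = self._ref_means[n] / mean_n
            total += vals * scale
            factor = (
                self._ref_means[n] / self._ref_means_grid[n]
                if self.norm == "reference"
                else 1.0
            )
            mean_grid_norm += vals.mean() * scale * factor
        return total, mean_grid_norm

    def net_values(self, params: np.ndarray) -> np.ndarray:
        """Flat net-field values over the evaluator grid (uFOV-normalized)."""
        return self._accumulate(params)[0]

    def cost_of_poses(self, poses: list[FiberPose]) -> float:
        params = np.array(
            [[q.R, q.theta, q.phi, q.dx, q.dy] for q in poses]
        ).ravel()
        return self(params)

    def __call__(self, params: np.ndarray) -> float:
        vals, mean_large = self._accumulate(params)
        inside = vals[self._ufov_idx]
        mean_in = inside.mean()
        if self.cost == "cv":
            if self.cv_mode == "std":
                return float(inside.std() / mean_in)
            return float(inside.var() / mean_in)
        term1 = 1.0 - mean_in / inside.max()
        if self.cost == "mean_max":
            return float(term1)
        ratio = mean_large / mean_in
        if self.efficiency_mode == "literal":
            ratio = 1.0 / ratio
        return float(term1 + ratio)
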