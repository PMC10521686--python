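"""Genetic-seeded generalized pattern search over fiber placements.

The design problem minimizes the illumination cost over five parameters per
fiber (R, theta, phi, dx, dy; 20 parameters for the four-fiber system).  A
small genetic algorithm first scans the bounded parameter space for a good
basin; a generalized pattern search (GPS) then refines it: the 2d signed
coordinate directions are polled at the current mesh size, the incumbent
moves on the first improvement (doubling the mesh), and the mesh halves
after a full unsuccessful poll.  Search terminates when the mesh size or
the accepted step drops below tolerance, or when the evaluation budget is
exhausted.

All search happens in coordinates normalized to [0, 1] per parameter;
azimuths are treated as periodic.  Results depend only on the seed and the
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("lumiplan.optimize")

from .cost import CostEvaluator, UFOVSpec
from .fields import EmitterSpec, FiberPose, PlaneGrid

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "RepeatabilityStudy",
    "genetic_seed",
    "pattern_search",
    "optimize_illumination",
    "repeatability_study",
]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "R": (12.5, 40.0),
    "theta": (30.0, 60.0),
    "phi": (0.0, 360.0),
    "dx": (-5.0, 5.0),
    "dy": (-5.0, 5.0),
}

_PARAM_ORDER = ("R", "theta", "phi", "dx", "dy")


@dataclass(frozen=True)
class OptimizationConfig:
    """Bounds, budgets, tolerances and GA settings for a design search."""

    n_fibers: int = 4
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_evaluations: int = 50_000
    mesh_tolerance: float = 1e-6
    step_tolerance: float = 1e-6
    initial_mesh: float = 0.25
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

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be at least 1")
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be at least 1")
        if self.mesh_tolerance <= 0 or self.step_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        for name in _PARAM_ORDER:
            lo, hi = self.bounds[name]
            if lo >= hi:
                raise ValueError(f"bound for {name!r} has lower >= upper: {lo} >= {hi}")

    def vector_bounds(self) -> np.ndarray:
        """(5*n_fibers, 2) array of per-coordinate bounds."""
        per_fiber = np.array([self.bounds[name] for name in _PARAM_ORDER])
        return np.tile(per_fiber, (self.n_fibers, 1))

    def periodic_mask(self) -> np.ndarray:
        """Marks azimuth coordinates, which wrap instead of clipping."""
        mask = np.zeros(5 * self.n_fibers, dtype=bool)
        mask[2::5] = True
        return mask


@dataclass
class OptimizationResult:
    """Outcome of one search: best point, diagnostics and cost trace.

    ``cost_trace`` records (evaluation index, best cost so far) at every
    improvement; the best cost is non-increasing along it.  ``poses`` is
    populated when the search was over fiber-pose parameters.
    """

    x: np.ndarray
    final_cost: float
    n_evaluations: int
    termination_reason: str  # mesh_tol | step_tol | max_evals
    cost_trace: list[tuple[int, float]]
    seed: int
    poses: list[FiberPose] | None = None

    def poses_array(self) -> np.ndarray:
        return np.array([[p.R, p.theta, p.phi, p.dx, p.dy] for p in self.poses])


class _Budget:
    """Counts evaluations against a cap, in physical coordinates."""

    def __init__(self, fn, max_evaluations: int):
        self.fn = fn
        self.max_evaluations = max_evaluations
        self.count = 0
        self.best = np.inf
        self.trace: list[tuple[int, float]] = []

    def exhausted(self) -> bool:
        return self.count >= self.max_evaluations

    def __call__(self, x: np.ndarray) -> float:
        self.count += 1
        val = float(self.fn(x))
        if val < self.best:
            self.best = val
            self.trace.append((self.count, val))
        return val


def _decode(u: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    return lo + u * span


def genetic_seed(
    cost_fn,
    config: OptimizationConfig,
    budget: _Budget | None = None,
) -> np.ndarray:
    """Best candidate from a small bounded genetic algorithm.

    Tournament selection (k=3), uniform crossover, Gaussian mutation
    (sigma = 0.1 of the parameter range, per-gene probability 0.2) with a
    single elite carried over; deterministic given ``config.seed``.  Returns
    the best parameter vector in physical units.
    """
    rng = np.random.default_rng(config.seed)
    vb = config.vector_bounds()
    lo, span = vb[:, 0], vb[:, 1] - vb[:, 0]
    periodic = config.periodic_mask()
    if budget is None:
        budget = _Budget(cost_fn, config.max_evaluations)
        fn = budget
    else:
        fn = budget
    pop_n = config.ga_population
    d = lo.size

    pop = rng.random((pop_n, d))
    fit = np.array([fn(_decode(u, lo, span)) for u in pop])

    for _ in range(config.ga_generations):
        if budget.exhausted():
            break
        order = np.argsort(fit)
        new_pop = [pop[order[0]].copy()]  # elite
        while len(new_pop) < pop_n:
            # tournament selection of two parents
            parents = []
            for _p in range(2):
                contenders = rng.integers(0, pop_n, size=3)
                parents.append(pop[contenders[np.argmin(fit[contenders])]])
            # uniform crossover
            take = rng.random(d) < 0.5
            child = np.where(take, parents[0], parents[1]).copy()
            # bounded Gaussian mutation
            mutate = rng.random(d) < 0.2
            child[mutate] += rng.normal(0.0, 0.1, size=int(mutate.sum()))
            child[periodic] %= 1.0
            np.clip(child, 0.0, 1.0, out=child)
            new_pop.append(child)
        pop = np.array(new_pop)
        fit = np.empty(pop_n)
        fit[0] = fn(_decode(pop[0], lo, span))
        for i in range(1, pop_n):
            if budget.exhausted():
                fit[i:] = np.inf
                break
            fit[i] = fn(_decode(pop[i], lo, span))

    return _decode(pop[np.argmin(fit)], lo, span)


def pattern_search(
    cost_fn,
    start: np.ndarray,
    config: OptimizationConfig,
    bounds: np.ndarray | None = None,
    budget: _Budget | None = None,
) -> OptimizationResult:
    """Generalized pattern search from ``start`` (physical units).

    Polls the 2d signed coordinate directions at the current mesh size
    (normalized units), opportunistically: the first improving poll is
    accepted, the mesh doubles (capped at 1), and the successful direction
    is polled first next time.  A full unsuccessful poll halves the mesh.
    Polls are clipped to the bounds (azimuths wrap).  Terminates on mesh
    size < ``mesh_tolerance``, accepted step < ``step_tolerance``, or the
    evaluation budget.
    """
    vb = config.vector_bounds() if bounds is None else np.asarray(bounds, dtype=float)
    lo, span = vb[:, 0], vb[:, 1] - vb[:, 0]
    d = lo.size
    periodic = (
        config.periodic_mask() if bounds is None else np.zeros(d, dtype=bool)
    )
    start = np.asarray(start, dtype=float)
    if start.size != d:
        raise ValueError(f"start has size {start.size}, expected {d}")
    u = (start - lo) / span
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("start point lies outside the bounds")
    u = np.clip(u, 0.0, 1.0)

    if budget is None:
        budget = _Budget(cost_fn, config.max_evaluations)
    f_inc = budget(_decode(u, lo, span))
    mesh = config.initial_mesh
    reason = "max_evals"
    # poll order: indices into the 2d direction set, successful first
    dir_order = list(range(2 * d))

    while True:
        if budget.exhausted():
            reason = "max_evals"
            break
        success = False
        for k, di in enumerate(list(dir_order)):
            coord, sign = divmod(di, 2)
            step = mesh if sign == 0 else -mesh
            trial = u.copy()
            trial[coord] += step
            if periodic[coord]:
                trial[coord] %= 1.0
            else:
                trial[coord] = min(max(trial[coord], 0.0), 1.0)
            step_len = abs(trial[coord] - u[coord])
            if step_len < config.step_tolerance:
                continue  # clipped onto (or next to) the incumbent: a no-op
            if budget.exhausted():
                break
            f_trial = budget(_decode(trial, lo, span))
            if f_trial < f_inc:
                u, f_inc = trial, f_trial
                mesh = min(mesh * 2.0, 1.0)
                dir_order.insert(0, dir_order.pop(k))
                success = True
                if step_len < config.step_tolerance and mesh < config.step_tolerance:
                    reason = "step_tol"
                break
        if success:
            if reason == "step_tol":
                break
            continue
        if budget.exhausted():
            reason = "max_evals"
            break
        mesh *= 0.5
        if mesh < config.mesh_tolerance:
            reason = "mesh_tol"
            break

    x = _decode(u, lo, span)
    poses = None
    if bounds is None and d == 5 * config.n_fibers:
        poses = [
            FiberPose(*x[5 * i : 5 * i + 5]) for i in range(config.n_fibers)
        ]
    return OptimizationResult(
        x=x,
        final_cost=f_inc,
        n_evaluations=budget.count,
        termination_reason=reason,
        cost_trace=budget.trace,
        seed=config.seed,
        poses=poses,
    )


def optimize_illumination(
    emitters: list[EmitterSpec] | EmitterSpec,
    ufov: UFOVSpec,
    grid_spec: PlaneGrid | float | None = None,
    config: OptimizationConfig | None = None,
) -> OptimizationResult:
    """Full design optimization: genetic seed, then pattern-search refinement.

    ``grid_spec`` fixes the search-grid pitch (a grid or a pitch in mm;
    default ``config.search_pitch``).  The cost named in the config
    (combined, mean_max or cv) is minimized over the 5N pose parameters;
    the shared evaluation budget covers both phases.
    """
    if config is None:
        config = OptimizationConfig()
    if isinstance(emitters, EmitterSpec):
        emitters = [emitters] * config.n_fibers
    if len(emitters) != config.n_fibers:
        raise ValueError(
            f"got {len(emitters)} emitters for n_fibers={config.n_fibers}"
        )
    if grid_spec is None:
        pitch = config.search_pitch
    elif isinstance(grid_spec, PlaneGrid):
        pitch = grid_spec.pixel_pitch
    else:
        pitch = float(grid_spec)
    evaluator = CostEvaluator(
        emitters,
        ufov,
        pixel_pitch=pitch,
        cost=config.cost,
        efficiency_mode=config.efficiency_mode,
        cv_mode=config.cv_mode,
        norm=config.norm,
        term_normalization=config.term_normalization,
        shift_mode=config.shift_mode,
    )
    budget = _Budget(evaluator, config.max_evaluations)
    x0 = genetic_seed(evaluator, config, budget=budget)
    logger.info(
        "genetic seed: best cost %.6f after %d evaluations",
        budget.best, budget.count,
    )
    result = pattern_search(evaluator, x0, config, budget=budget)
    logger.info(
        "pattern search: cost %.6f, %d evaluations, %s",
        result.final_cost, result.n_evaluations, result.termination_reason,
    )
    return result


@dataclass
class RepeatabilityStudy:
    """Several independent optimizations of one design problem."""

    results: list[OptimizationResult]
    pairwise_correlations: np.ndarray  # condensed upper-triangle Pearson r
    evaluation_counts: list[int]

    @property
    def min_correlation(self) -> float:
        return float(self.pairwise_correlations.min())


def repeatability_study(
    emitters: list[EmitterSpec] | EmitterSpec,
    ufov: UFOVSpec,
    grid_spec: PlaneGrid | float | None = None,
    config: OptimizationConfig | None = None,
    n_runs: int = 5,
    seeds: list[int] | None = None,
) -> RepeatabilityStudy:
    """Run the design optimization ``n_runs`` times with consecutive seeds.

    ``seeds`` overrides the default ``config.seed .. config.seed+n_runs-1``
    sequence (repeating a seed reproduces a run exactly).  Similarity is
    summarized as the Pearson correlation between every pair of final
    fields rendered within the uFOV at the report pitch.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    if config is None:
        config = OptimizationConfig()
    if seeds is None:
        seeds = [config.seed + k for k in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError(f"got {len(seeds)} seeds for n_runs={n_runs}")
    results = [
        optimize_illumination(
            emitters, ufov, grid_spec, replace(config, seed=s)
        )
        for s in seeds
    ]
    if isinstance(emitters, EmitterSpec):
        emitters = [emitters] * config.n_fibers
    from .fields import irradiance_net

    grid = ufov.grid(config.report_pitch)
    fields = [
        irradiance_net(
            res.poses, emitters, grid, shift_mode=config.shift_mode
        ).values.ravel()
        for res in results
    ]
    corr = []
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            corr.append(float(np.corrcoef(fields[i], fields[j])[0, 1]))
    return RepeatabilityStudy(
        results=results,
        pairwise_correlations=np.array(corr),
        evaluation_counts=[r.n_evaluations for r in results],
    )
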