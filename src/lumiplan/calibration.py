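"""Viewing half-angle calibration against a fluorescence-standard image.

A fiber's effective Lambertian exponent is recovered by least squares:
a uniform fluorescent slide is imaged under a single fiber at a known
pose, and the viewing half-angle of the simulated field is adjusted until
the simulated and measured intensity patterns agree.  Both patterns are
background-subtracted and max-normalized before comparison, since absolute
detector gain is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .fields import EmitterSpec, FiberPose, PlaneGrid, irradiance_single

__all__ = ["CalibrationImage", "CalibrationBoundError", "fit_half_angle", "HalfAngleModel", "CalibrationResult"]


class CalibrationBoundError(RuntimeError):
    """The best-fit half-angle sits on a search bound (fit not trusted)."""


@dataclass
class CalibrationImage:
    """A single-fiber standard-slide frame with its known pose.

    ``image`` is the measured intensity grid (2-D array, any linear scale);
    ``pixel_pitch`` is mm per pixel; ``background`` the constant offset to
    subtract (default: the 1st percentile of the frame).
    """

    image: np.ndarray
    pose: FiberPose
    pixel_pitch: float
    background: float | None = None
    shift_mode: str = "translate"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("calibration image must be a 2-D single channel")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.background is None:
            self.background = float(np.percentile(self.image, 1.0))
        if self.image.max() <= self.background:
            raise ValueError("image maximum does not exceed the background level")

    def grid(self) -> PlaneGrid:
        ny, nx = self.image.shape
        return PlaneGrid(nx * self.pixel_pitch, ny * self.pixel_pitch,
                         self.pixel_pitch)

    def normalized(self) -> np.ndarray:
        vals = np.clip(self.image - self.background, 0.0, None)
        return vals / vals.max()


def fit_half_angle(
    cal: CalibrationImage,
    bounds: tuple[float, float] = (1.0, 30.0),
    xatol: float = 1e-6,
) -> tuple[float, float]:
    """Least-squares estimate of the viewing half-angle (degrees).

    Minimizes the sum of squared differences between the max-normalized
    measured frame and the max-normalized simulated field of the known
    pose, over the half-angle within ``bounds``, using bounded scalar
    minimization.  Returns ``(half_angle_deg, sse)``.

    Raises :class:`CalibrationBoundError` if the optimum lands on a bound,
    which signals a mis-posed calibration rather than a usable estimate.
    """
    lo, hi = bounds
    if not 0 < lo < hi < 90:
        raise ValueError(f"invalid half-angle bounds {bounds}")
    grid = cal.grid()
    measured = cal.normalized()

    def sse(half_angle: float) -> float:
        sim = irradiance_single(
            cal.pose, EmitterSpec(half_angle), grid, shift_mode=cal.shift_mode
        ).values
        smax = sim.max()
        if smax == 0.0:
            return float(np.sum(measured**2))
        return float(np.sum((measured - sim / smax) ** 2))

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    half = float(res.x)
    if half - lo < 10 * xatol or hi - half < 10 * xatol:
        raise CalibrationBoundError(
            f"fitted half-angle {half:.4f} deg lies on the search bound {bounds}"
        )
    return half, float(res.fun)


@dataclass
class CalibrationResult:
    """Fitted emitter for one fiber, with the residual of the fit."""

    half_angle: float
    m: float
    sse: float
    pose: FiberPose
    bounds: tuple[float, float]

    def summary(self) -> str:
        return (
            "Half-angle calibration\n"
            f"  half-angle : {self.half_angle:8.3f} deg (bounds {self.bounds})\n"
            f"  exponent m : {self.m:8.2f}\n"
            f"  residual   : {self.sse:8.3e} (sum of squares, normalized units)\n"
            f"  pose       : R={self.pose.R} mm, theta={self.pose.theta} deg, "
            f"phi={self.pose.phi} deg"
        )

    @property
    def emitter(self) -> EmitterSpec:
        return EmitterSpec(self.half_angle)


class HalfAngleModel:
    """Model object for half-angle calibration: ``fit()`` returns results.

    Parameters mirror :class:`CalibrationImage`; the model holds the data
    and fitting bounds, ``fit`` performs the bounded least-squares scan.
    """

    def __init__(
        self,
        image: np.ndarray,
        pose: FiberPose,
        pixel_pitch: float,
        background: float | None = None,
        bounds: tuple[float, float] = (1.0, 30.0),
        shift_mode: str = "translate",
    ) -> None:
        self.data = CalibrationImage(image, pose, pixel_pitch, background,
                                     shift_mode)
        self.bounds = bounds

    def fit(self) -> CalibrationResult:
        from .fields import m_from_half_angle

        half, sse = fit_half_angle(self.data, self.bounds)
        return CalibrationResult(
            half_angle=half,
            m=m_from_half_angle(half),
            sse=sse,
            pose=self.data.pose,
            bounds=self.bounds,
        )
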