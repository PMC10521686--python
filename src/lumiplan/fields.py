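"""Lambertian fiber-source irradiance on the sample plane.

Each optical fiber is modeled as a Lambertian emitter: relative radiant
intensity falls off as ``cos^m`` of the viewing angle, where the exponent
``m`` is set by the fiber's viewing half-angle (the off-axis angle at which
intensity drops to half its on-axis value).  A fiber pose is given in
spherical coordinates about the sample-plane origin — radial distance ``R``
(mm), polar angle ``theta`` from the +z axis, azimuth ``phi`` from the +x
axis — plus an in-plane shift ``(dx, dy)`` of the beam center.  The fiber
boresight points at the (pre-shift) origin.

Irradiance is evaluated on a planar raster at z = 0 and is relative
(dimensionless): unit on-axis amplitude with inverse-square falloff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmitterSpec",
    "FiberPose",
    "PlaneGrid",
    "IrradianceField",
    "m_from_half_angle",
    "half_angle_from_m",
    "irradiance_single",
    "irradiance_net",
]

#: Smallest supported viewing half-angle in degrees; narrower emitters give
#: astronomically large exponents and numerically degenerate fields.
MIN_HALF_ANGLE_DEG = 0.1


def m_from_half_angle(half_angle: float) -> float:
    """Lambertian exponent from the viewing half-angle (degrees).

    ``m = -ln 2 / ln(cos(half_angle))``, so that the cos^m intensity profile
    drops to one half exactly at the half-angle.  Monotonically decreasing:
    narrow beams have large ``m`` (an ideal cosine emitter, 60 deg, has m=1).
    """
    if not 0.0 < half_angle < 90.0:
        raise ValueError(
            f"half_angle must lie strictly between 0 and 90 degrees, got {half_angle}"
        )
    return -math.log(2.0) / math.log(math.cos(math.radians(half_angle)))


def half_angle_from_m(m: float) -> float:
    """Inverse of :func:`m_from_half_angle`: half-angle in degrees from ``m``."""
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    return math.degrees(math.acos(2.0 ** (-1.0 / m)))


@dataclass(frozen=True)
class EmitterSpec:
    """A Lambertian emitter defined by its viewing half-angle (degrees).

    The exponent ``m`` is derived and cached; supplying ``m`` explicitly is
    allowed but it must be consistent with the half-angle to 1e-9 relative.
    """

    half_angle: float
    m: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not MIN_HALF_ANGLE_DEG <= self.half_angle < 90.0:
            raise ValueError(
                f"half_angle must be in [{MIN_HALF_ANGLE_DEG}, 90) degrees, "
                f"got {self.half_angle}"
            )
        m_true = m_from_half_angle(self.half_angle)
        if self.m is None:
            object.__setattr__(self, "m", m_true)
        elif abs(self.m - m_true) > 1e-9 * m_true:
            raise ValueError(
                f"m={self.m} inconsistent with half_angle={self.half_angle} "
                f"(expected {m_true})"
            )


@dataclass(frozen=True)
class FiberPose:
    """Spherical-coordinate placement of one fiber source.

    R : mm, radial source-origin distance (> 0)
    theta : degrees, polar angle from +z, in [0, 90)
    phi : degrees, azimuth from +x about z, reduced to [0, 360)
    dx, dy : mm, shift of the beam center in the sample plane
    """

    R: float
    theta: float
    phi: float
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if not 0.0 <= self.theta < 90.0:
            raise ValueError(f"theta must be in [0, 90) degrees, got {self.theta}")
        object.__setattr__(self, "phi", float(self.phi) % 360.0)

    @property
    def source_position(self) -> np.ndarray:
        """Cartesian (x, y, z) of the fiber tip, mm."""
        th = math.radians(self.theta)
        ph = math.radians(self.phi)
        return np.array(
            [
                self.R * math.sin(th) * math.cos(ph),
                self.R * math.sin(th) * math.sin(ph),
                self.R * math.cos(th),
            ]
        )


@dataclass(frozen=True)
class PlaneGrid:
    """Cell-centered raster covering a rectangle centered on the origin.

    ``extent_x`` and ``extent_y`` are full widths (mm); sample (i, j) sits at
    the center of its cell.  ``z`` is fixed at 0 (the sample plane).
    """

    extent_x: float
    extent_y: float
    pixel_pitch: float = 0.05
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        if self.nx < 3 or self.ny < 3:
            raise ValueError(
                f"grid must have at least 3 samples per axis, got {self.nx}x{self.ny}"
            )

    @property
    def nx(self) -> int:
        return int(round(self.extent_x / self.pixel_pitch))

    @property
    def ny(self) -> int:
        return int(round(self.extent_y / self.pixel_pitch))

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (ny, nx)."""
        return (self.ny, self.nx)

    def x_coords(self) -> np.ndarray:
        n = self.nx
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def y_coords(self) -> np.ndarray:
        n = self.ny
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (ny, nx); row index varies along y."""
        return np.meshgrid(self.x_coords(), self.y_coords(), indexing="xy")

    def rect_mask(self, width: float, height: float) -> np.ndarray:
        """Boolean mask of cells whose centers lie in a centered w x h box."""
        x = self.x_coords()
        y = self.y_coords()
        mx = np.abs(x) <= width / 2.0 + 1e-12
        my = np.abs(y) <= height / 2.0 + 1e-12
        return np.outer(my, mx)


@dataclass
class IrradianceField:
    """Relative irradiance sampled on a :class:`PlaneGrid` (values >= 0)."""

    grid: PlaneGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("irradiance values must be finite and non-negative")

    def mean(self, mask: np.ndarray | None = None) -> float:
        return float(self.values.mean() if mask is None else self.values[mask].mean())

    def max(self, mask: np.ndarray | None = None) -> float:
        return float(self.values.max() if mask is None else self.values[mask].max())

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))

    def save_png_preview(self, path) -> None:
        """8-bit max-normalized preview."""
        import imageio.v3 as iio

        vmax = self.values.max()
        img = np.zeros_like(self.values) if vmax == 0 else self.values / vmax
        iio.imwrite(str(path), (img * 255).round().astype(np.uint8))


def _single_values(
    pose: FiberPose,
    emitter: EmitterSpec,
    X: np.ndarray,
    Y: np.ndarray,
    shift_mode: str = "translate",
) -> np.ndarray:
    """cos^m(psi)/r^2 for one source over sample-plane points (X, Y).

    ``shift_mode="aim"``: the fiber boresight points at the beam center
    (dx, dy, 0), so the off-center spot is dimmer and distorted by the
    longer, more oblique throw.  ``shift_mode="translate"``: the dx=dy=0
    pattern is rigidly translated by (dx, dy) in the plane.
    """
    S = pose.source_position
    if shift_mode == "aim":
        b = np.array([pose.dx, pose.dy, 0.0]) - S
        b /= math.sqrt(b @ b)
        vx = X - S[0]
        vy = Y - S[1]
        vz = -S[2]
        d2 = vx * vx + vy * vy + vz * vz
        if np.any(d2 == 0.0):
            raise ValueError("grid point coincides with the source position")
        cospsi = (vx * b[0] + vy * b[1] + vz * b[2]) / np.sqrt(d2)
    elif shift_mode == "translate":
        shat = S / pose.R
        vx = S[0] - (X - pose.dx)
        vy = S[1] - (Y - pose.dy)
        vz = S[2]
        d2 = vx * vx + vy * vy + vz * vz
        if np.any(d2 == 0.0):
            raise ValueError("grid point coincides with the source position")
        cospsi = (vx * shat[0] + vy * shat[1] + vz * shat[2]) / np.sqrt(d2)
    else:
        raise ValueError(f"unknown shift_mode {shift_mode!r}")
    out = np.zeros_like(d2)
    front = cospsi > 0.0
    out[front] = np.exp(emitter.m * np.log(cospsi[front])) / d2[front]
    return out


def irradiance_single(
    pose: FiberPose,
    emitter: EmitterSpec,
    grid: PlaneGrid,
    shift_mode: str = "translate",
) -> IrradianceField:
    """Irradiance of a single fiber on the sample plane.

    For each grid point P = (x, y, 0), with source S and beam-shifted
    evaluation point P' = (x - dx, y - dy, 0):

        E = max(0, cos psi)^m / |S - P'|^2,
        cos psi = ((S - P') . S/R) / |S - P'|

    i.e. the cosine of the angle between the fiber boresight (aimed at the
    origin) and the ray to the evaluation point; points behind the emitter
    hemisphere clamp to zero.  With the default ``shift_mode="aim"`` the
    beam-center shift (dx, dy) re-aims the boresight at (dx, dy, 0);
    ``"translate"`` rigidly shifts the dx=dy=0 pattern instead.
    """
    X, Y = grid.meshgrid()
    return IrradianceField(grid, _single_values(pose, emitter, X, Y, shift_mode))


def irradiance_net(
    poses: list[FiberPose],
    emitters: list[EmitterSpec] | EmitterSpec,
    grid: PlaneGrid,
    region: np.ndarray | None = None,
    ref_R: float = 5.0,
    norm: str = "reference",
    shift_mode: str = "translate",
) -> IrradianceField:
    """Net irradiance of N sources, normalized against a short-R reference.

    The per-source reference field ``E_ref,n`` is that of an on-axis source
    at a short working distance ``ref_R`` (same emitter, theta=phi=0,
    dx=dy=0) evaluated on the same grid.  Two normalizations are available:

    ``norm="reference"`` (default)
        ``E_net = sum_n E_n / mean(E_ref,n)`` — each source is divided by
        the average intensity it would deliver from the reference distance,
        a per-emitter constant.  Closer sources therefore contribute more
        power, preserving the physical 1/R^2 dependence.
    ``norm="field"``
        ``E_net = sum_n [E_n / mean(E_n)] * mean(E_ref,n)`` — each source is
        rescaled so its own regional mean matches the reference mean; all
        sources then contribute equally on the region.

    ``region`` selects the normalization region (boolean mask on the grid);
    ``None`` means the full grid.  During design optimization the region is
    the uFOV; for rendering and power comparisons the full frame is used.
    """
    if isinstance(emitters, EmitterSpec):
        emitters = [emitters] * len(poses)
    if len(poses) != len(emitters):
        raise ValueError("poses and emitters must have the same length")
    if len(poses) == 0:
        raise ValueError("at least one source is required")
    if norm not in ("reference", "field"):
        raise ValueError(f"unknown norm {norm!r}")
    X, Y = grid.meshgrid()
    if region is None:
        region = np.ones(grid.shape, dtype=bool)
    total = np.zeros(grid.shape)
    ref_means: dict[float, float] = {}
    for pose, emitter in zip(poses, emitters):
        vals = _single_values(pose, emitter, X, Y, shift_mode)
        if emitter.m not in ref_means:
            ref = _single_values(FiberPose(ref_R, 0.0, 0.0), emitter, X, Y)
            ref_means[emitter.m] = float(ref[region].mean())
        if norm == "reference":
            total += vals / ref_means[emitter.m]
        else:
            m_n = vals[region].mean()
            if m_n == 0.0:
                raise ValueError(
                    "source contributes zero mean irradiance on the region"
                )
            total += vals * (ref_means[emitter.m] / m_n)
    return IrradianceField(grid, total)
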