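"""Synthetic benchtop inputs: every physical measurement, rendered in silico.

The generators emulate the frames the bench produces — standard
fluorescence slides under a given illumination field, an optical-density
step wedge, fluorophore dilution phantoms, pre/post-injection pairs — so
the full analysis pipeline runs with no external data.  The detector model
is linear with optional Poisson shot noise and Gaussian read noise,
clipping and quantization to the bit depth; every generator is
bit-reproducible given its seed.

Defaults mirror the bench conditions: an 8-bit camera, shot noise on,
read noise of 1 DN, a 41-step wedge spanning optical densities 0.1-4, and
a 0-25 uM dilution series with three replicate frames per level.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .fields import EmitterSpec, FiberPose, IrradianceField, PlaneGrid, irradiance_net
from .metrics import DetectorImage

__all__ = [
    "DetectorModel",
    "SceneSpec",
    "render_frame",
    "make_standard_slide",
    "make_step_wedge",
    "make_phantom_series",
    "make_unoptimized_config",
    "make_pre_post_pair",
]


@dataclass(frozen=True)
class DetectorModel:
    """Linear camera model: gain, noise, clipping, quantization.

    ``gain`` converts expected photon signal to digital numbers (DN).
    Shot noise draws the photon signal from a Poisson law; read noise adds
    zero-mean Gaussian counts of width ``read_noise`` DN.  ``quantize``
    rounds to integer DN and clips to the bit range; turning it off gives
    an idealized linear float detector (useful for analytic checks).  A
    ``gamma`` hook exists for non-linear response but defaults to 1
    (the bench camera is linear over its dynamic range).
    """

    bit_depth: int = 8
    gain: float = 1.0
    read_noise: float = 1.0
    shot_noise: bool = True
    quantize: bool = True
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.read_noise < 0:
            raise ValueError("read_noise must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


IDEAL_DETECTOR = DetectorModel(shot_noise=False, read_noise=0.0, quantize=False)


@dataclass
class SceneSpec:
    """One renderable scene: illumination x fluorophore map on a detector.

    ``illumination`` may be an :class:`IrradianceField` or a plain 2-D
    array of relative irradiance; ``fluorophore_map`` is the relative
    fluorophore concentration per pixel (scalar for a uniform slab).
    """

    illumination: IrradianceField | np.ndarray
    fluorophore_map: np.ndarray | float
    detector: DetectorModel = dataclass_field(default_factory=DetectorModel)
    seed: int = 0

    def illumination_values(self) -> np.ndarray:
        if isinstance(self.illumination, IrradianceField):
            return self.illumination.values
        return np.asarray(self.illumination, dtype=float)


def render_frame(scene: SceneSpec) -> DetectorImage:
    """Render one camera frame from a scene.

    Expected signal is ``gain * illumination * fluorophore_map`` (DN);
    shot noise replaces it with a Poisson draw, read noise adds Gaussian
    counts, and the result is clipped and quantized per the detector.
    Deterministic for a fixed scene seed.
    """
    illum = scene.illumination_values()
    fluor = np.asarray(scene.fluorophore_map, dtype=float)
    if fluor.ndim == 2 and fluor.shape != illum.shape:
        raise ValueError(
            f"fluorophore map shape {fluor.shape} does not match "
            f"illumination {illum.shape}"
        )
    if np.any(fluor < 0):
        raise ValueError("fluorophore concentrations must be non-negative")
    det = scene.detector
    expected = det.gain * illum * fluor
    if det.gamma != 1.0:
        expected = expected**det.gamma
    rng = np.random.default_rng(scene.seed)
    signal = expected.astype(float)
    if det.shot_noise:
        signal = rng.poisson(expected).astype(float)
    if det.read_noise > 0:
        signal = signal + rng.normal(0.0, det.read_noise, size=signal.shape)
    signal = np.clip(signal, 0, det.max_value)
    if det.quantize:
        signal = np.round(signal)
    pitch = (
        scene.illumination.grid.pixel_pitch
        if isinstance(scene.illumination, IrradianceField)
        else 1.0
    )
    return DetectorImage(signal, pixel_pitch=pitch, bit_depth=det.bit_depth)


def make_standard_slide(
    poses: list[FiberPose],
    emitters: list[EmitterSpec] | EmitterSpec,
    grid: PlaneGrid,
    detector: DetectorModel | None = None,
    seed: int = 0,
    gain_to_fullscale: float = 0.9,
    shift_mode: str = "translate",
) -> DetectorImage:
    """A uniform fluorescent slide imaged under the net illumination field.

    The fluorophore map is 1 everywhere, so the frame is the illumination
    pattern itself as the camera sees it; exposure is set so the brightest
    pixel reaches ``gain_to_fullscale`` of the bit range before noise.
    """
    detector = detector or DetectorModel()
    fld = irradiance_net(poses, emitters, grid, shift_mode=shift_mode)
    scale = gain_to_fullscale * detector.max_value / fld.values.max()
    scene = SceneSpec(
        illumination=IrradianceField(grid, fld.values * scale),
        fluorophore_map=1.0,
        detector=detector,
        seed=seed,
    )
    return render_frame(scene)


def make_step_wedge(
    n_steps: int = 41,
    od_range: tuple[float, float] = (0.1, 4.0),
    detector: DetectorModel | None = None,
    shape: tuple[int, int] = (32, 32),
    exposure: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[DetectorImage]]:
    """Transmission step-wedge frames for dynamic-range calibration.

    Optical densities are linearly spaced over ``od_range``; each step
    transmits ``10**-OD`` of a uniform source and is rendered through the
    detector.  Returns ``(transmissions, frames)``.
    """
    detector = detector or DetectorModel()
    ods = np.linspace(od_range[0], od_range[1], n_steps)
    transmissions = 10.0 ** (-ods)
    if exposure is None:
        # brightest step near full scale
        exposure = 0.95 * detector.max_value / transmissions.max()
    frames = []
    for k, t in enumerate(transmissions):
        scene = SceneSpec(
            illumination=np.full(shape, exposure * t),
            fluorophore_map=1.0,
            detector=detector,
            seed=seed + k,
        )
        frames.append(render_frame(scene))
    return transmissions, frames


def make_phantom_series(
    concentrations: np.ndarray | None = None,
    detector: DetectorModel | None = None,
    illumination: IrradianceField | np.ndarray | None = None,
    shape: tuple[int, int] = (32, 32),
    n_replicates: int = 3,
    gain_per_uM: float = 9.0,
    background: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[list[DetectorImage]]]:
    """Fluorophore dilution phantoms with replicate frames per level.

    Concentrations default to six levels spanning 0-25 uM with a linear
    fluorescence response of ``gain_per_uM`` DN/uM plus a small constant
    background; three frames are rendered per phantom.  Returns
    ``(concentrations, frames_per_level)``.
    """
    if concentrations is None:
        concentrations = np.linspace(0.0, 25.0, 6)
    concentrations = np.asarray(concentrations, dtype=float)
    detector = detector or DetectorModel()
    if illumination is None:
        illumination = np.ones(shape)
    series: list[list[DetectorImage]] = []
    for i, c in enumerate(concentrations):
        reps = []
        for r in range(n_replicates):
            scene = SceneSpec(
                illumination=illumination,
                fluorophore_map=np.full(
                    np.shape(illumination.values
                             if isinstance(illumination, IrradianceField)
                             else illumination),
                    gain_per_uM * c + background,
                ),
                detector=detector,
                seed=seed + 1000 * i + r,
            )
            reps.append(render_frame(scene))
        series.append(reps)
    return concentrations, series


def make_unoptimized_config(
    poses: list[FiberPose], mode: str
) -> list[FiberPose]:
    """Degrade an optimized design the way the bench controls did.

    ``mode="z_shift_6mm"``: translate every fiber 6 mm along +z with its
    orientation fixed, as physically raising the fiber holder does.  The
    source's lateral position is preserved (R and theta recomputed) and,
    because the beam keeps pointing along its old axis, each beam center
    overshoots through the origin to the far side: the center lands at
    (dx, dy) + (dz/Sz) * ((dx, dy) - S_xy).  This is what destroys the
    pattern's uniformity on the bench.
    ``mode="zero_offsets"``: zero every beam-center shift so all spots
    collapse onto the origin.
    """
    import math

    if mode == "zero_offsets":
        return [FiberPose(p.R, p.theta, p.phi, 0.0, 0.0) for p in poses]
    if mode == "z_shift_6mm":
        dz = 6.0
        out = []
        for p in poses:
            S = p.source_position
            z_new = S[2] + dz
            lateral = math.hypot(S[0], S[1])
            R_new = math.sqrt(lateral**2 + z_new**2)
            theta_new = math.degrees(math.atan2(lateral, z_new))
            dx_new = p.dx + (dz / S[2]) * (p.dx - S[0])
            dy_new = p.dy + (dz / S[2]) * (p.dy - S[1])
            out.append(FiberPose(R_new, theta_new, p.phi, dx_new, dy_new))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def make_pre_post_pair(
    illumination: IrradianceField | np.ndarray,
    uptake_fold: float,
    mask: np.ndarray,
    detector: DetectorModel | None = None,
    base_level: float = 40.0,
    seed: int = 0,
) -> tuple[DetectorImage, DetectorImage]:
    """Pre/post-injection frame pair with known probe uptake.

    The post frame multiplies the fluorophore map by ``uptake_fold``
    inside ``mask`` (the uptake region); outside, nothing changes.  The
    pre frame's fluorophore level is ``base_level`` DN under unit
    illumination.
    """
    if uptake_fold < 0:
        raise ValueError("uptake_fold must be non-negative")
    illum_vals = (
        illumination.values
        if isinstance(illumination, IrradianceField)
        else np.asarray(illumination, dtype=float)
    )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != illum_vals.shape:
        raise ValueError("mask must be congruent with the illumination")
    detector = detector or DetectorModel()
    fluor_pre = np.full(illum_vals.shape, base_level)
    fluor_post = fluor_pre.copy()
    fluor_post[mask] *= uptake_fold
    pre = render_frame(
        SceneSpec(illumination, fluor_pre, detector, seed=seed)
    )
    post = render_frame(
        SceneSpec(illumination, fluor_post, detector, seed=seed + 1)
    )
    return pre, post
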