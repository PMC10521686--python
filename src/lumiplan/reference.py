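"""Reference four-fiber designs used as fixtures and benchmarks.

These are the optimized fiber placements for the two illumination
geometries the four-fiber bench system was built around: a low-aspect-ratio
6 x 6 mm uniform field of view (window-chamber tumors, organoids) and a
high-aspect-ratio 4 x 12 mm one (core-needle biopsies), together with the
calibrated viewing half-angles of the four physical fibers.
"""

from __future__ import annotations

from .cost import UFOVSpec
from .fields import EmitterSpec, FiberPose

#: Calibrated viewing half-angles of the four bench fibers (degrees).
FIBER_HALF_ANGLES_DEG: tuple[float, ...] = (6.09, 6.29, 6.08, 6.00)

#: Optimized poses for the low-aspect-ratio 6 x 6 mm design
#: (R mm, theta deg, phi deg, dx mm, dy mm; one row per fiber).
LOW_AR_POSES: tuple[FiberPose, ...] = (
    FiberPose(12.72, 47.38, 2.12, 0.85, 1.74),
    FiberPose(13.30, 45.24, 95.80, -1.33, 1.04),
    FiberPose(12.53, 46.03, 181.40, -0.68, -1.51),
    FiberPose(12.52, 45.00, 270.32, 1.99, -0.65),
)

#: Optimized poses for the high-aspect-ratio 4 x 12 mm design.
HIGH_AR_POSES: tuple[FiberPose, ...] = (
    FiberPose(23.43, 31.33, 57.66, 0.03, 1.12),
    FiberPose(20.00, 38.31, 160.15, -0.06, 4.75),
    FiberPose(20.25, 58.22, 268.53, -0.28, -2.96),
    FiberPose(22.28, 46.94, 287.37, 0.35, -3.11),
)

LOW_AR_UFOV = UFOVSpec(6.0, 6.0)
HIGH_AR_UFOV = UFOVSpec(4.0, 12.0)


def reference_emitters() -> list[EmitterSpec]:
    """Emitters with the four calibrated bench half-angles."""
    return [EmitterSpec(h) for h in FIBER_HALF_ANGLES_DEG]
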