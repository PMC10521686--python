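"""Quantification of illumination and fluorescence images.

The suite covers the measurements used to validate a uniform-illumination
design on the bench: gradient-magnitude maps (uniformity), extraction of
the uniform-illumination region, intensity histograms normalized across
configurations, mean-power ratios, pixel-wise flat-field correction,
signal-to-background ratio (SBR) of pre/post-injection pairs, specific/
nonspecific probe-contrast survival curves, and detector-linearity
regression.  All ratio metrics are invariant to a common positive rescale
of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage, stats
from skimage import measure as skmeasure

__all__ = [
    "DetectorImage",
    "RegionMask",
    "MaskProvenance",
    "gradient_magnitude_map",
    "uniform_region",
    "normalized_histogram",
    "power_ratio",
    "flat_field_correct",
    "sbr",
    "probe_contrast_survival",
    "SurvivalCurves",
    "compare_survival",
    "linearity_fit",
]


class MaskProvenance(str, Enum):
    UFOV_BOX = "ufov_box"
    UNIFORM_BOX = "uniform_box"
    MANUAL = "manual"
    TUMOR_RING = "tumor_ring"


@dataclass
class DetectorImage:
    """A quantized camera frame: single-channel pixels plus geometry.

    RGB input is reduced to one channel on construction (default green,
    matching a green emission filter).  ``bit_depth`` bounds the pixel
    range; ``pixel_pitch`` is mm per pixel.
    """

    pixels: np.ndarray
    pixel_pitch: float = 1.0
    bit_depth: int = 8
    channel: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            px = px[..., self.channel]
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grid or an RGB stack")
        px = px.astype(float)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        vmax = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > vmax:
            raise ValueError(
                f"pixel values outside the {self.bit_depth}-bit range [0, {vmax}]"
            )
        self.pixels = px

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @classmethod
    def from_file(cls, path, pixel_pitch: float = 1.0, channel: int = 1
                  ) -> "DetectorImage":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(str(path)))
        bit_depth = 16 if raw.dtype.itemsize > 1 else 8
        return cls(raw, pixel_pitch=pixel_pitch, bit_depth=bit_depth,
                   channel=channel)


@dataclass
class RegionMask:
    """A boolean region congruent with an image."""

    mask: np.ndarray
    provenance: MaskProvenance = MaskProvenance.MANUAL

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bbox(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1), half-open, of the True region."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1

    def to_rle(self) -> dict:
        """Run-length encoding (row-major, starting with a False run)."""
        flat = self.mask.ravel()
        changes = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
        bounds = np.concatenate([[0], changes, [flat.size]])
        runs = np.diff(bounds).tolist()
        if flat[0]:
            runs = [0] + runs
        return {
            "shape": list(self.mask.shape),
            "runs": runs,
            "provenance": self.provenance.value,
        }

    @classmethod
    def from_rle(cls, payload: dict) -> "RegionMask":
        shape = tuple(payload["shape"])
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        pos, value = 0, False
        for run in payload["runs"]:
            if value:
                flat[pos : pos + run] = True
            pos += run
            value = not value
        if pos != flat.size:
            raise ValueError("run lengths do not cover the mask")
        return cls(flat.reshape(shape),
                   MaskProvenance(payload.get("provenance", "manual")))


def _as_array(image) -> np.ndarray:
    if isinstance(image, DetectorImage):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    return arr


def gradient_magnitude_map(image, smooth_window: int = 0) -> np.ndarray:
    """Gradient-magnitude image: sqrt(gx^2 + gy^2) per pixel.

    Optionally Gaussian-smooths first (``smooth_window`` pixels wide,
    sigma = window/6), then takes central differences (one-sided at the
    borders).  A uniformly illuminated center shows up as a near-zero
    plateau.
    """
    arr = _as_array(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    if smooth_window:
        arr = ndimage.gaussian_filter(arr, sigma=smooth_window / 6.0)
    gy, gx = np.gradient(arr)
    return np.sqrt(gx * gx + gy * gy)


def uniform_region(image, threshold: float = 0.9) -> RegionMask:
    """Bounding box of the uniform-illumination region.

    Pixels within 10% of the frame maximum (value >= threshold * max) form
    the candidate set; the box is taken around its largest 8-connected
    component.  Ties on component size resolve to the component holding
    the global maximum, then to the smallest (row, column) index.
    """
    arr = _as_array(image)
    vmax = arr.max()
    if vmax <= 0:
        raise ValueError("image maximum must be positive")
    candidate = arr >= threshold * vmax
    labels = skmeasure.label(candidate, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    top = np.flatnonzero(sizes == sizes[best])
    if top.size > 1:
        argmax_label = labels[np.unravel_index(int(arr.argmax()), arr.shape)]
        if argmax_label in top:
            best = int(argmax_label)
        else:
            # smallest row-then-column first pixel among tied components
            first = {
                lab: np.unravel_index(int((labels == lab).argmax()), arr.shape)
                for lab in top
            }
            best = int(min(top, key=lambda lab: first[lab]))
    comp = labels == best
    box = np.zeros_like(comp)
    rows = np.flatnonzero(comp.any(axis=1))
    cols = np.flatnonzero(comp.any(axis=0))
    box[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] = True
    return RegionMask(box, MaskProvenance.UNIFORM_BOX)


def normalized_histogram(
    image, mask: np.ndarray | RegionMask | None, ref_max: float, bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of intensities scaled by a reference maximum.

    Pixels inside ``mask`` (typically the uFOV) are divided by ``ref_max``
    — the maximum of the reference configuration, so that histograms of
    different configurations share one intensity axis — and binned as a
    density.  Returns ``(bin_edges, density)``.
    """
    if ref_max <= 0:
        raise ValueError("ref_max must be positive")
    arr = _as_array(image)
    if mask is None:
        vals = arr.ravel()
    else:
        m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
        if not m.any():
            raise ValueError("mask selects no pixels")
        vals = arr[m]
    scaled = vals / ref_max
    hi = max(1.0, float(scaled.max()))
    density, edges = np.histogram(scaled, bins=bins, range=(0.0, hi),
                                  density=True)
    return edges, density


def power_ratio(field_a, mask_a, field_b, mask_b) -> float:
    """Mean-intensity fold change of configuration a over configuration b.

    Both fields are first scaled by the maximum of ``field_a`` (a common
    factor, so the ratio itself is scale-free); the result is
    mean(a within mask_a) / mean(b within mask_b).
    """
    a = _as_array(field_a)
    b = _as_array(field_b)
    ma = mask_a.mask if isinstance(mask_a, RegionMask) else np.asarray(mask_a, bool)
    mb = mask_b.mask if isinstance(mask_b, RegionMask) else np.asarray(mask_b, bool)
    if not ma.any() or not mb.any():
        raise ValueError("masks must select at least one pixel")
    ref = a.max()
    if ref <= 0:
        raise ValueError("field_a maximum must be positive")
    mean_b = (b / ref)[mb].mean()
    if mean_b == 0:
        raise ValueError("field_b mean is zero on its mask")
    return float((a / ref)[ma].mean() / mean_b)


def flat_field_correct(
    sample: DetectorImage, standard: DetectorImage, floor: float = 0.05
) -> tuple[DetectorImage, RegionMask]:
    """Divide out the illumination pattern measured on a standard slide.

    The standard frame is max-normalized and clipped below at ``floor``
    (to avoid blow-up where illumination is essentially absent); the
    sample is divided pixel-by-pixel and rescaled back to its bit range.
    Returns the corrected image and a validity mask marking pixels where
    the standard was at or above the floor (elsewhere the correction is
    unreliable).
    """
    s = sample.pixels
    st = standard.pixels
    if s.shape != st.shape:
        raise ValueError(f"shape mismatch: sample {s.shape} vs standard {st.shape}")
    if not 0 < floor < 1:
        raise ValueError("floor must be in (0, 1)")
    st_norm = st / st.max()
    valid = st_norm >= floor
    corrected = s / np.maximum(st_norm, floor)
    vmax = sample.max_value
    cmax = corrected.max()
    if cmax > 0:
        corrected = corrected * (vmax / cmax)
    out = DetectorImage(np.clip(corrected, 0, vmax),
                        pixel_pitch=sample.pixel_pitch,
                        bit_depth=sample.bit_depth)
    return out, RegionMask(valid, MaskProvenance.MANUAL)


def sbr(pre_image, post_image, mask) -> float:
    """Signal-to-background ratio of an injection pair.

    Mean post-injection intensity divided by mean pre-injection intensity
    over the same region; unitless.
    """
    pre = _as_array(pre_image)
    post = _as_array(post_image)
    if pre.shape != post.shape:
        raise ValueError("pre and post images must be congruent")
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("mask selects no pixels")
    denom = pre[m].mean()
    if denom == 0:
        raise ValueError("pre-injection (background) mean is zero")
    return float(post[m].mean() / denom)


@dataclass
class SurvivalCurves:
    """Empirical survival (1 - CDF) of the specific/nonspecific pixel ratio.

    ``grid`` is the common ratio axis; ``per_image`` holds one survival
    curve per specific-probe image (evaluated on the grid); ``mean`` and
    ``sem`` summarize across images; ``pooled_ratios`` collects every
    pixel ratio for distribution-level comparisons.
    """

    grid: np.ndarray
    per_image: np.ndarray
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)
    pooled_ratios: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mean = self.per_image.mean(axis=0)
        n = self.per_image.shape[0]
        self.sem = (
            self.per_image.std(axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else np.zeros_like(self.mean)
        )


def probe_contrast_survival(
    specific_images: list,
    nonspecific_images: list,
    masks: list | None = None,
    grid_points: int = 512,
) -> SurvivalCurves:
    """Probe-specificity survival curves from two image cohorts.

    Every pixel of each specific-probe image is divided by the grand mean
    intensity of all nonspecific-probe images; the empirical survival
    function (1 - CDF) of those ratios is computed per image on a common
    grid, with the across-image mean +/- SEM.  ``masks``, if given, select
    the analysed pixels of each specific image.
    """
    if not specific_images or not nonspecific_images:
        raise ValueError("both cohorts must be non-empty")
    ns_vals = np.concatenate([_as_array(im).ravel() for im in nonspecific_images])
    denom = ns_vals.mean()
    if denom == 0:
        raise ValueError("nonspecific cohort mean is zero")
    ratio_sets = []
    for k, im in enumerate(specific_images):
        arr = _as_array(im)
        if masks is not None:
            m = masks[k]
            m = m.mask if isinstance(m, RegionMask) else np.asarray(m, bool)
            arr = arr[m]
        ratio_sets.append(arr.ravel() / denom)
    pooled = np.concatenate(ratio_sets)
    lo, hi = 0.0, float(pooled.max()) * 1.001
    grid = np.linspace(lo, hi, grid_points)
    per_image = np.vstack(
        [1.0 - np.searchsorted(np.sort(r), grid, side="right") / r.size
         for r in ratio_sets]
    )
    return SurvivalCurves(grid=grid, per_image=per_image, pooled_ratios=pooled)


def compare_survival(a: SurvivalCurves, b: SurvivalCurves) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on the pooled pixel ratios.

    Returns ``(statistic, p_value)``; the statistic is the maximum
    vertical distance between the two empirical distributions.
    """
    res = stats.ks_2samp(a.pooled_ratios, b.pooled_ratios)
    return float(res.statistic), float(res.pvalue)


def linearity_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of mean intensity against known level.

    Returns ``(slope, intercept, r_squared)``.  Used for detector
    dynamic-range checks (step-wedge transmission) and fluorophore
    dilution series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x levels are degenerate (zero spread)")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
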