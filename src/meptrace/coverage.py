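"""Coverage of the motor-endplate region by an intramuscular tracer.

Per muscle section, the tracer (CTB) channel is segmented by binarization
followed by hole filling, the endplate (MEP) channel by filtering followed
by binarization, and the two binary masks are multiplied.  Coverage is the
ratio of MEP-signal pixels that fall inside the tracer region to all
MEP-signal pixels; per-depth coverages are averaged (unweighted) into a
mean coverage per muscle/strategy.

Thresholds may be automatic (Otsu) or manual, mirroring the per-image
manual adjustment used in practice.  Hole filling uses 4-connected
background (8-connected foreground): every background region not reachable
from the image border becomes foreground.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryMask:
    pixels: np.ndarray  # 2D bool
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.dtype != bool:
            raise ValueError("pixels must be a 2D boolean array")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ThresholdSpec:
    """Binarization threshold: automatic (Otsu) or a fixed manual value."""

    mode: str = "auto"  # "auto" | "manual"
    manual_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "manual"):
            raise ValueError(f"unknown threshold mode: {self.mode!r}")
        if (self.mode == "manual") != (self.manual_value is not None):
            raise ValueError("manual_value must be set iff mode == 'manual'")

    @classmethod
    def auto(cls) -> "ThresholdSpec":
        return cls(mode="auto")

    @classmethod
    def manual(cls, value: float) -> "ThresholdSpec":
        return cls(mode="manual", manual_value=value)

    def resolve(self, image: np.ndarray) -> float | None:
        """Threshold value for an image; None if no threshold is separable."""
        if self.mode == "manual":
            return float(self.manual_value)
        if np.all(image == image.flat[0]):
            return None
        return float(threshold_otsu(image))


@dataclass(frozen=True)
class FilterSpec:
    """Pre-binarization filter for the endplate channel."""

    kind: str = "median"  # "median" | "none"
    size: int = 3

    def apply(self, image: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return image
        if self.kind == "median":
            return ndimage.median_filter(image, size=self.size)
        raise ValueError(f"unknown filter kind: {self.kind!r}")


@dataclass(frozen=True)
class DepthCoverage:
    depth_um: float
    coverage: float  # NaN when the MEP mask is empty (excluded from mean)
    mep_pixels: int
    mep_pixels_in_ctb: int


@dataclass(frozen=True)
class CoverageResult:
    per_depth: tuple[DepthCoverage, ...]
    mean_coverage: float


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    return img


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background: 4-connected background flood from the border.

    Never removes foreground and never alters background connected to the
    image border.
    """
    return ndimage.binary_fill_holes(
        mask, structure=ndimage.generate_binary_structure(2, 1))


def segment_tracer_region(
    image: np.ndarray,
    threshold_spec: ThresholdSpec | None = None,
    pixel_size_um: float = 1.0,
) -> BinaryMask:
    """Segment the tracer diffusion region: binarize, then fill holes.

    A constant image under auto thresholding has no separable threshold and
    yields an empty mask with a warning.
    """
    img = _check_image(image)
    spec = threshold_spec or ThresholdSpec.auto()
    thr = spec.resolve(img)
    if thr is None:
        warnings.warn("constant image: no threshold separable, empty tracer "
                      "mask", stacklevel=2)
        return BinaryMask(np.zeros(img.shape, dtype=bool), pixel_size_um)
    logger.debug("tracer threshold used: %g (%s)", thr, spec.mode)
    return BinaryMask(fill_holes(img > thr), pixel_size_um)


def segment_mep_signal(
    image: np.ndarray,
    filter_spec: FilterSpec | None = None,
    threshold_spec: ThresholdSpec | None = None,
    pixel_size_um: float = 1.0,
) -> BinaryMask:
    """Segment the endplate signal: filter (default 3×3 median), binarize.

    No hole filling is applied to the endplate channel.
    """
    img = _check_image(image)
    filt = (filter_spec or FilterSpec()).apply(img)
    spec = threshold_spec or ThresholdSpec.auto()
    thr = spec.resolve(filt)
    if thr is None:
        warnings.warn("constant image: no threshold separable, empty MEP "
                      "mask", stacklevel=2)
        return BinaryMask(np.zeros(img.shape, dtype=bool), pixel_size_um)
    logger.debug("MEP threshold used: %g (%s)", thr, spec.mode)
    return BinaryMask(filt > thr, pixel_size_um)


class EmptyMEPMaskError(ValueError):
    """Coverage is undefined when there is no endplate signal."""


def coverage_ratio(mep_mask: BinaryMask | np.ndarray,
                   ctb_mask: BinaryMask | np.ndarray) -> float:
    """Fraction of MEP pixels inside the tracer region.

    Computed as the pixel count of the elementwise mask product over the MEP
    pixel count.  Raises :class:`EmptyMEPMaskError` on an empty MEP mask
    (coverage is undefined, never silently 0).
    """
    mep = mep_mask.pixels if isinstance(mep_mask, BinaryMask) else np.asarray(mep_mask, dtype=bool)
    ctb = ctb_mask.pixels if isinstance(ctb_mask, BinaryMask) else np.asarray(ctb_mask, dtype=bool)
    if mep.shape != ctb.shape:
        raise ValueError(f"mask shapes differ: {mep.shape} vs {ctb.shape}")
    n_mep = int(mep.sum())
    if n_mep == 0:
        raise EmptyMEPMaskError("MEP mask is empty: coverage undefined")
    n_in = int((mep & ctb).sum())
    return n_in / n_mep


def coverage_profile(
    sections,
    filter_spec: FilterSpec | None = None,
    threshold_spec: ThresholdSpec | None = None,
    tracer_threshold_spec: ThresholdSpec | None = None,
) -> CoverageResult:
    """Per-depth coverage and its unweighted mean over a list of sections.

    ``sections`` is a sequence of :class:`~meptrace.synth.imaging.SectionImage`
    (or objects with ``depth_um`` and ``channels['tracer'/'mep']``).
    ``threshold_spec`` applies to the endplate channel;
    ``tracer_threshold_spec`` (default: same policy) to the tracer channel.
    Sections with an empty endplate mask are recorded with NaN coverage and
    excluded from the mean, with a logged warning.
    """
    sections = list(sections)
    if not sections:
        raise ValueError("need at least one section")
    depths = [s.depth_um for s in sections]
    if len(set(depths)) != len(depths):
        raise ValueError("section depths must be distinct")
    tracer_spec = tracer_threshold_spec or threshold_spec

    per_depth: list[DepthCoverage] = []
    valid: list[float] = []
    for s in sections:
        ctb = segment_tracer_region(s.channels["tracer"], tracer_spec,
                                    s.pixel_size_um)
        mep = segment_mep_signal(s.channels["mep"], filter_spec,
                                 threshold_spec, s.pixel_size_um)
        if mep.count == 0:
            logger.warning("depth %g μm: empty MEP mask, coverage undefined; "
                           "excluded from mean", s.depth_um)
            per_depth.append(DepthCoverage(s.depth_um, float("nan"), 0, 0))
            continue
        cov = coverage_ratio(mep, ctb)
        n_in = int((mep.pixels & ctb.pixels).sum())
        per_depth.append(DepthCoverage(s.depth_um, cov, mep.count, n_in))
        valid.append(cov)
    mean_cov = float(np.mean(valid)) if valid else float("nan")
    return CoverageResult(per_depth=tuple(per_depth), mean_coverage=mean_cov)


def invert_for_display(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Inverted rendering of a mask (dark signal on light background).

    Purely cosmetic; all counts are computed on the un-inverted masks.
    """
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    return ~px
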