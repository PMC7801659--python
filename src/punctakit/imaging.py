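"""Registration, segmentation and morphometry of fluorescent puncta.

Puncta (bright, roughly disc-shaped protein condensates) are segmented
from single-channel fluorescence images by global automatic thresholding,
and described by the standard particle-analysis shape descriptors:
area, perimeter, circularity, roundness, aspect ratio and solidity.
Whole-cell and per-punctum fluorescence are summarised as background-
corrected integrated densities (CTCF / CTFP).

Conventions: coordinates are 0-based ``(row, col) = (y, x)``; areas are
converted to square micrometres via ``pixel_size**2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation


class RegistrationWarning(UserWarning):
    pass


class GeometryWarning(UserWarning):
    pass


@dataclass(frozen=True)
class RoiMask:
    """Boolean pixel mask congruent with a single image frame."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("RoiMask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, pixel_size: float) -> float:
        """ROI area in µm²: true-pixel count times the pixel area."""
        return self.n_pixels * pixel_size**2

    def __and__(self, other: "RoiMask") -> "RoiMask":
        return RoiMask(self.mask & other.mask)

    def __invert__(self) -> "RoiMask":
        return RoiMask(~self.mask)


@dataclass
class ImageStack:
    """Time-ordered single-channel image stack with acquisition metadata.

    Parameters
    ----------
    pixels : (T, Y, X) array of intensities.
    timestamps : acquisition times in seconds, strictly increasing.
    pixel_size : lateral pixel size in µm/pixel.
    bleach_frame_index : index of the first post-bleach frame, or None
        for stacks without a bleach event.
    stimulation_roi : the laser stimulation region, or None.
    """

    pixels: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    bleach_frame_index: int | None = None
    stimulation_roi: RoiMask | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (T, Y, X) array")
        if len(self.timestamps) != self.pixels.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bleach_frame_index is not None and not (
            0 <= self.bleach_frame_index < self.pixels.shape[0]
        ):
            raise ValueError("bleach_frame_index out of range")
        if self.stimulation_roi is not None and (
            self.stimulation_roi.mask.shape != self.pixels.shape[1:]
        ):
            raise ValueError("stimulation_roi shape must match frames")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PunctumRecord:
    """Shape and fluorescence descriptors of one segmented punctum."""

    punctum_id: int
    cell_id: int
    area: float  # µm²
    perimeter: float  # µm
    circularity: float
    roundness: float
    solidity: float
    aspect_ratio: float
    centroid: tuple[float, float]  # (row, col) in pixels
    integrated_density: float
    ctfp: float = 0.0
    border_warning: bool = False


@dataclass
class CellRecord:
    """Per-cell fluorescence summary."""

    cell_id: int
    ctcf: float
    puncta_count: int = 0
    percent_punctate: float = float("nan")
    ctcf_negative: bool = field(default=False)


# ---------------------------------------------------------------------------
# registration


def register_stack(
    stack: ImageStack, upsample_factor: int = 20
) -> tuple[ImageStack, list[tuple[float, float]]]:
    """Align every frame to the first frame by translation.

    Shifts are estimated by phase cross-correlation with subpixel
    refinement and applied with spline interpolation; pixels shifted in
    from outside the field are filled with the frame's median intensity
    (a robust background estimate). Returns the registered stack and the
    per-frame applied shifts ``(dy, dx)``.
    """
    if stack.n_frames < 2:
        warnings.warn("single-frame stack: registration is a no-op", RegistrationWarning)
        return stack, [(0.0, 0.0)] * stack.n_frames

    ref = stack.pixels[0].astype(float)
    out = np.empty_like(stack.pixels, dtype=float)
    out[0] = ref
    shifts: list[tuple[float, float]] = [(0.0, 0.0)]
    for t in range(1, stack.n_frames):
        frame = stack.pixels[t].astype(float)
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        fill = float(np.median(frame))
        out[t] = ndimage.shift(frame, shift, order=1, mode="constant", cval=fill)
        shifts.append((float(shift[0]), float(shift[1])))
    registered = ImageStack(
        pixels=out,
        timestamps=stack.timestamps,
        pixel_size=stack.pixel_size,
        bleach_frame_index=stack.bleach_frame_index,
        stimulation_roi=stack.stimulation_roi,
    )
    return registered, shifts


# ---------------------------------------------------------------------------
# segmentation and morphometry


def segment_puncta(
    image: np.ndarray,
    pixel_size: float,
    min_area_px: int = 4,
    cell_id: int = 0,
) -> tuple[np.ndarray, list[PunctumRecord]]:
    """Segment puncta by Otsu thresholding of a 3x3-median-filtered image.

    Connected components (8-connectivity) smaller than ``min_area_px``
    are discarded. Returns the label image and one record per punctum.
    A blank or constant image yields zero puncta.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=int), []
    # the median filter stabilises the threshold estimate against shot
    # noise; the threshold is applied to the raw image so small puncta
    # are not eroded
    smoothed = median_filter(img, footprint=np.ones((3, 3), dtype=bool))
    thr = threshold_otsu(smoothed)
    binary = img > thr
    labels = cc_label(binary, connectivity=2)
    records: list[PunctumRecord] = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_id = 1
    for rp in regionprops(labels, intensity_image=img):
        if rp.area < min_area_px:
            continue
        keep[rp.label] = next_id
        rec = measure_punctum(rp, pixel_size, punctum_id=next_id, cell_id=cell_id)
        records.append(rec)
        next_id += 1
    return keep[labels], records


def circularity(area: float, perimeter: float) -> float:
    """``4π·area/perimeter²``, clipped to 1 (pixelated contours can
    otherwise exceed it). A circle gives exactly 1, a square π/4."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def roundness(area: float, major_axis: float) -> float:
    """``4·area/(π·major_axis²)``: 1 for a circle, <1 for elongation."""
    if major_axis <= 0:
        raise ValueError("major_axis must be positive")
    return 4.0 * area / (np.pi * major_axis**2)


def _measure_from_regionprops(rp, pixel_size: float, punctum_id: int, cell_id: int) -> PunctumRecord:
    area_px = float(rp.area)
    perim_px = float(rp.perimeter)
    if area_px <= 1 or perim_px == 0:
        # single-pixel (or degenerate) component: marching-squares perimeter
        # is 0, so circularity is 1 by convention
        circ = 1.0
        perim_px = max(perim_px, 4.0 * np.sqrt(area_px))
    else:
        circ = circularity(area_px, perim_px)
    major = float(rp.axis_major_length)
    minor = float(rp.axis_minor_length)
    rnd = roundness(area_px, major) if major > 0 else 1.0
    aspect = major / minor if minor > 0 else 1.0
    integ = float(rp.image_intensity[rp.image].sum()) if rp.image_intensity is not None else 0.0
    return PunctumRecord(
        punctum_id=punctum_id,
        cell_id=cell_id,
        area=area_px * pixel_size**2,
        perimeter=perim_px * pixel_size,
        circularity=circ,
        roundness=min(1.0, rnd),
        solidity=min(1.0, float(rp.solidity)),
        aspect_ratio=max(1.0, aspect),
        centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
        integrated_density=integ,
    )


def measure_punctum(
    component,
    pixel_size: float,
    punctum_id: int = 1,
    cell_id: int = 0,
) -> PunctumRecord:
    """Compute shape descriptors for one connected component.

    ``component`` is either a skimage ``RegionProperties`` object or a
    boolean pixel mask. Descriptors follow the particle-analysis
    conventions: circularity ``4π·area/perimeter²`` (clipped at 1,
    because pixelated discs can exceed 1 with contour-length
    perimeters), roundness ``4·area/(π·major_axis²)``, aspect ratio
    ``major/minor`` and solidity ``area/convex hull area``.
    """
    if isinstance(component, np.ndarray):
        mask = np.asarray(component, dtype=bool)
        if not mask.any():
            raise ValueError("empty component")
        rps = regionprops(mask.astype(int), intensity_image=mask.astype(float))
        return _measure_from_regionprops(rps[0], pixel_size, punctum_id, cell_id)
    return _measure_from_regionprops(component, pixel_size, punctum_id, cell_id)


# ---------------------------------------------------------------------------
# fluorescence statistics


def integrated_density(image: np.ndarray, roi: RoiMask) -> float:
    """Sum of pixel intensities over the ROI."""
    return float(np.asarray(image, dtype=float)[roi.mask].sum())


def compute_ctcf(
    image: np.ndarray, cell_mask: RoiMask, background_mask: RoiMask
) -> CellRecord:
    """Corrected total cell fluorescence.

    CTCF = integrated density over the cell mask minus
    (cell area in pixels) x (mean background intensity). A negative
    CTCF is allowed but flagged on the returned record.
    """
    if background_mask.n_pixels == 0:
        raise ValueError("background mask is empty")
    if (cell_mask.mask & background_mask.mask).any():
        raise ValueError("cell and background masks must be disjoint")
    img = np.asarray(image, dtype=float)
    integ = img[cell_mask.mask].sum()
    bg_mean = img[background_mask.mask].mean()
    ctcf = float(integ - cell_mask.n_pixels * bg_mean)
    return CellRecord(cell_id=0, ctcf=ctcf, ctcf_negative=ctcf < 0)


def compute_ctfp(
    image: np.ndarray, punctum_mask: RoiMask, background_mean: float
) -> float:
    """Corrected total fluorescence of a punctum (punctum-level CTCF)."""
    img = np.asarray(image, dtype=float)
    return float(img[punctum_mask.mask].sum() - punctum_mask.n_pixels * background_mean)


def percent_punctate_fluorescence(
    puncta: list[PunctumRecord], cell: CellRecord
) -> float:
    """Percent of a cell's fluorescence residing in its puncta.

    100 x (sum of per-punctum CTFP) / CTCF. Requires CTCF > 0.
    """
    if cell.ctcf <= 0:
        raise ValueError("percent punctate fluorescence requires CTCF > 0")
    total_ctfp = sum(p.ctfp for p in puncta)
    return 100.0 * total_ctfp / cell.ctcf


def area_circularity_trend(records: list[PunctumRecord]) -> tuple[float, float]:
    """OLS slope and intercept of circularity regressed on area.

    Used to quantify whether larger puncta tend to be less circular
    (negative slope).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 puncta")
    areas = np.array([r.area for r in records], dtype=float)
    circ = np.array([r.circularity for r in records], dtype=float)
    if np.ptp(areas) == 0:
        raise ValueError("zero variance in areas")
    slope, intercept = np.polyfit(areas, circ, 1)
    return float(slope), float(intercept)
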