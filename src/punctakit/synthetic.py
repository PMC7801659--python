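"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the four kinds of raw data the pipeline consumes:

* time-lapse FRAP stacks of a photobleached punctum whose bleached
  region recovers as ``A·(1 − exp(−t/τ))``;
* fixed-cell images with a known number of puncta and a known fraction
  of fluorescence residing in puncta;
* punctum-area samples from a two-component normal mixture;
* densitometry tables with a known insoluble percentage, and sigmoidal
  ThT aggregation traces with a known half-transition time.

All randomness is driven by explicit integer seeds; there is no global
random state. Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .biochem import DensitometryRow, KineticTrace
from .imaging import ImageStack, PunctumRecord, RoiMask

# Component parameters (µm²) of the two-population punctum-area mixtures
# for the three brain-expressed ubiquilins, eGFP-tagged, in live cells.
# P1 is the small-punctum population, P2 the large one; P1 comprises
# 37-43% of puncta, so simulations use weights (0.40, 0.60).
PUNCTA_AREA_MIXTURES: dict[str, dict[str, tuple[float, float]]] = {
    "UBQLN1": {"means": (0.8, 11.2), "sds": (0.6, 10.1)},
    "UBQLN2": {"means": (0.4, 8.4), "sds": (0.3, 8.1)},
    "UBQLN4": {"means": (0.9, 14.8), "sds": (0.8, 10.7)},
}
DEFAULT_MIXTURE_WEIGHTS: tuple[float, float] = (0.40, 0.60)


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# acquisition schedule


@dataclass(frozen=True)
class AcquisitionSchedule:
    """FRAP acquisition timing.

    Defaults mirror the confocal protocol: 5 pre-bleach frames every
    2 s, then after the bleach 12 frames every 5 s (1 min of fine
    sampling over the rising phase) followed by 36 frames every 10 s
    (6 min). ``t = 0`` is the first post-bleach frame; pre-bleach frames
    carry negative timestamps.
    """

    n_prebleach: int = 5
    prebleach_interval_s: float = 2.0
    post_phases: tuple[tuple[int, float], ...] = ((12, 5.0), (36, 10.0))

    def __post_init__(self) -> None:
        if self.n_prebleach < 5:
            raise ValidationError("at least 5 pre-bleach frames required")
        if not self.post_phases or sum(n for n, _ in self.post_phases) < 1:
            raise ValidationError("at least one post-bleach frame required")

    def timestamps(self) -> np.ndarray:
        """Times in seconds, 0 at the first post-bleach frame."""
        pre = -self.prebleach_interval_s * np.arange(self.n_prebleach, 0, -1)
        post: list[float] = []
        t = 0.0
        for n, dt in self.post_phases:
            for _ in range(n):
                post.append(t)
                t += dt
        return np.concatenate([pre, np.array(post)])

    @property
    def bleach_frame_index(self) -> int:
        return self.n_prebleach

    @property
    def n_frames(self) -> int:
        return self.n_prebleach + sum(n for n, _ in self.post_phases)


DEFAULT_SCHEDULE = AcquisitionSchedule()


# ---------------------------------------------------------------------------
# ground-truth specs


@dataclass(frozen=True)
class FrapGroundTruth:
    """Parameters generating one photobleached punctum.

    ``mobile_fraction`` (A) is the asymptotically recovering fraction of
    the bleached signal, ``half_time`` (τ, seconds) the exponential time
    constant of recovery, ``bleach_depth`` the post-bleach intensity in
    the stimulation ROI as a fraction of its pre-bleach value.
    """

    mobile_fraction: float = 0.7
    half_time: float = 60.0
    bleach_depth: float = 0.1
    punctum_center: tuple[float, float] = (32.0, 32.0)
    punctum_radius: float = 12.0  # px
    stimulation_roi_area: float = 5.5  # µm²
    background_level: float = 100.0
    punctum_level: float = 3000.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    acquisition_bleach_tau: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValidationError("mobile_fraction must be in [0, 1]")
        if self.half_time <= 0:
            raise ValidationError("half_time must be positive")
        if not 0.0 <= self.bleach_depth < 1.0:
            raise ValidationError("bleach_depth must be in [0, 1)")
        if self.punctum_radius <= 0:
            raise ValidationError("punctum_radius must be positive")


@dataclass(frozen=True)
class MixtureSpec:
    """A K-component univariate normal mixture to sample areas from."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    n: int
    seed: int = 0
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValidationError("weights, means and sds must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValidationError("weights must be non-negative")
        if any(s <= 0 for s in self.sds):
            raise ValidationError("sds must be positive")
        if self.n < 0:
            raise ValidationError("n must be non-negative")


@dataclass(frozen=True)
class ThtSpec:
    """A logistic ThT aggregation curve with known half-transition time."""

    baseline: float = 50.0
    plateau: float = 1000.0
    t_half: float = 12.0  # hours
    steepness: float = 1.0  # 1/hours
    noise_sd: float = 0.0
    timepoints: tuple[float, ...] = tuple(np.arange(0.0, 48.0 + 1e-9, 0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau == self.baseline:
            raise ValidationError("plateau must differ from baseline")
        if len(self.timepoints) < 3:
            raise ValidationError("need at least 3 timepoints")
        ts = np.asarray(self.timepoints)
        if not (ts.min() <= self.t_half <= ts.max()):
            raise ValidationError("t_half must lie within the time range")


@dataclass(frozen=True)
class SolubilityTruth:
    """Ground truth for one sample's soluble/insoluble partitioning."""

    sample_id: str
    percent_insoluble: float
    total_abundance: float = 100.0
    loading_noise_sd: float = 0.0
    band_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_insoluble <= 100.0:
            raise ValidationError("percent_insoluble must be in [0, 100]")


# ---------------------------------------------------------------------------
# punctum areas


def sample_puncta_areas(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``spec.n`` areas from the mixture; return (values, labels).

    Labels record the generating component. With ``truncate_at_zero``
    negative draws are rejected and redrawn (for use as image geometry);
    statistical-recovery fixtures use untruncated normals, matching the
    model the mixture fitter assumes, so ML estimates stay unbiased.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(len(spec.weights), size=spec.n, p=spec.weights)
    means = np.asarray(spec.means)[labels]
    sds = np.asarray(spec.sds)[labels]
    values = rng.normal(means, sds)
    if spec.truncate_at_zero:
        bad = values <= 0
        while bad.any():
            values[bad] = rng.normal(means[bad], sds[bad])
            bad = values <= 0
    return values, labels


# ---------------------------------------------------------------------------
# FRAP simulation


def recovery_curve(
    t: np.ndarray, mobile_fraction: float, half_time: float
) -> np.ndarray:
    """Normalized single-exponential recovery ``A·(1 − exp(−t/τ))``."""
    return mobile_fraction * (1.0 - np.exp(-np.asarray(t, dtype=float) / half_time))


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_frap_stack(
    truth: FrapGroundTruth,
    schedule: AcquisitionSchedule = DEFAULT_SCHEDULE,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 0.2,
    conserve_punctum: bool = False,
) -> tuple[ImageStack, FrapGroundTruth]:
    """Render a photobleaching time-lapse of one punctum.

    The punctum is a disc of ``punctum_level`` over ``background_level``.
    At the bleach frame, pixels inside the stimulation ROI drop to
    ``bleach_depth`` times their pre-bleach value; afterwards each such
    pixel recovers as ``I_b + A·(I_pre − I_b)·(1 − exp(−t/τ))`` with t
    measured from the first post-bleach frame.

    By default recovery is purely additive: all intensity outside the
    stimulation ROI is constant across frames. With
    ``conserve_punctum=True`` the recovered signal is instead drawn
    from the punctum's unbleached region — that region dims by exactly
    the amount the bleached region regains, keeping the total punctum
    intensity at its post-bleach value, as when recovery proceeds by
    redistribution of unbleached molecules within the punctum.

    Optional whole-frame acquisition photobleaching, rigid per-frame
    drift, and additive Gaussian noise are applied on top.
    """
    roi_radius_px = np.sqrt(truth.stimulation_roi_area / np.pi) / pixel_size
    stim = _disc_mask(shape, truth.punctum_center, roi_radius_px)
    if not stim.any() or (
        truth.punctum_center[0] - roi_radius_px < 0
        or truth.punctum_center[1] - roi_radius_px < 0
        or truth.punctum_center[0] + roi_radius_px >= shape[0]
        or truth.punctum_center[1] + roi_radius_px >= shape[1]
    ):
        raise ValidationError("stimulation ROI extends outside the image")
    punctum_area_um2 = np.pi * (truth.punctum_radius * pixel_size) ** 2
    if truth.stimulation_roi_area > (2.0 / 3.0) * punctum_area_um2 + 1e-9:
        raise ValidationError(
            "stimulation ROI must cover at most 2/3 of the punctum area"
        )

    rng = np.random.default_rng(truth.seed)
    punctum = _disc_mask(shape, truth.punctum_center, truth.punctum_radius)
    base = np.full(shape, truth.background_level, dtype=float)
    base[punctum] = truth.punctum_level
    donor = punctum & ~stim  # unbleached punctum region feeding recovery

    times = schedule.timestamps()
    frames = np.empty((schedule.n_frames, *shape), dtype=float)
    bleach_idx = schedule.bleach_frame_index
    i_pre = base[stim]
    i_bleached = truth.bleach_depth * i_pre
    for k, t in enumerate(times):
        frame = base.copy()
        if k >= bleach_idx:
            regain = truth.mobile_fraction * (i_pre - i_bleached) * (
                1.0 - np.exp(-t / truth.half_time)
            )
            frame[stim] = i_bleached + regain
            if conserve_punctum and donor.any():
                frame[donor] -= regain.sum() / donor.sum()
        if truth.acquisition_bleach_tau is not None:
            frame *= np.exp(-(t - times[0]) / truth.acquisition_bleach_tau)
        if truth.drift_per_frame != (0.0, 0.0):
            dy, dx = truth.drift_per_frame
            frame = ndimage.shift(
                frame, (dy * k, dx * k), order=1, mode="constant",
                cval=truth.background_level,
            )
        if truth.noise_sd > 0:
            frame = frame + rng.normal(0.0, truth.noise_sd, size=shape)
        frames[k] = frame

    stack = ImageStack(
        pixels=frames,
        timestamps=times,
        pixel_size=pixel_size,
        bleach_frame_index=bleach_idx,
        stimulation_roi=RoiMask(stim),
    )
    return stack, truth


def simulate_frap_trace(
    truth: FrapGroundTruth, schedule: AcquisitionSchedule = DEFAULT_SCHEDULE
):
    """Generate a raw FRAP intensity-ratio trace directly (no imaging).

    Pre-bleach ratio is 1; post-bleach values follow the bleach-and-
    recover model on the normalized scale, mapped back to the raw ratio
    scale via ``bleach_depth``. Gaussian noise of ``noise_sd`` is added
    on the raw ratio scale. Returns a :class:`~punctakit.frap.FrapTrace`.
    """
    from .frap import FrapTrace

    rng = np.random.default_rng(truth.seed)
    times = schedule.timestamps()
    n_pre = schedule.n_prebleach
    raw = np.empty_like(times)
    raw[:n_pre] = 1.0
    post_t = times[n_pre:]
    norm = recovery_curve(post_t, truth.mobile_fraction, truth.half_time)
    raw[n_pre:] = truth.bleach_depth + (1.0 - truth.bleach_depth) * norm
    if truth.noise_sd > 0:
        raw = raw + rng.normal(0.0, truth.noise_sd, size=raw.shape)
    return FrapTrace(
        timestamps=times,
        raw_values=raw,
        n_prebleach=n_pre,
    )


# ---------------------------------------------------------------------------
# fixed-cell images


@dataclass(frozen=True)
class FixedCellSpec:
    """Layout of one synthetic fixed cell.

    A total above-background signal budget ``cell_total_signal`` is
    split between a uniform cytoplasmic pool (``diffuse_fraction``) and
    the puncta (the remainder, divided evenly over punctum pixels on top
    of the diffuse level). The true punctate fraction of the cell is
    therefore ``1 − diffuse_fraction`` exactly.
    """

    shape: tuple[int, int] = (128, 128)
    cell_center: tuple[float, float] = (64.0, 64.0)
    cell_radius: float = 50.0
    puncta_centers: tuple[tuple[float, float], ...] = ()
    puncta_radii: tuple[float, ...] = ()
    diffuse_fraction: float = 0.5
    cell_total_signal: float = 1.0e6
    background_level: float = 20.0
    noise_sd: float = 0.0
    pixel_size: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.puncta_centers) != len(self.puncta_radii):
            raise ValidationError("one radius per punctum required")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValidationError("diffuse_fraction must be in [0, 1]")
        if self.diffuse_fraction < 1.0 and not self.puncta_centers:
            raise ValidationError(
                "puncta required when diffuse_fraction < 1"
            )


def simulate_fixed_cell_image(
    spec: FixedCellSpec,
) -> tuple[np.ndarray, list[PunctumRecord], float]:
    """Render a fixed cell and return (image, true puncta, true % punctate).

    Puncta must fit inside the cell disc; a punctum overlapping the cell
    border is rendered but flagged with ``border_warning``. The returned
    percentage is the puncta's exact share of above-background cell
    signal, ``100·(1 − diffuse_fraction)`` (0 when there are no puncta).
    """
    rng = np.random.default_rng(spec.seed)
    cell = _disc_mask(spec.shape, spec.cell_center, spec.cell_radius)
    img = np.full(spec.shape, spec.background_level, dtype=float)
    img[cell] += spec.diffuse_fraction * spec.cell_total_signal / cell.sum()

    records: list[PunctumRecord] = []
    cy, cx = spec.cell_center
    puncta_masks = []
    total_puncta_px = 0
    for i, ((py, px), r) in enumerate(zip(spec.puncta_centers, spec.puncta_radii)):
        if np.hypot(py - cy, px - cx) >= spec.cell_radius:
            raise ValidationError(f"punctum {i} lies outside the cell")
        disc = _disc_mask(spec.shape, (py, px), r) & cell
        puncta_masks.append(disc)
        total_puncta_px += int(disc.sum())

    puncta_budget = (1.0 - spec.diffuse_fraction) * spec.cell_total_signal
    per_px = puncta_budget / total_puncta_px if total_puncta_px else 0.0
    for i, (disc, (py, px), r) in enumerate(
        zip(puncta_masks, spec.puncta_centers, spec.puncta_radii)
    ):
        img[disc] += per_px
        border = bool(np.hypot(py - cy, px - cx) + r > spec.cell_radius)
        area_px = float(disc.sum())
        records.append(
            PunctumRecord(
                punctum_id=i + 1,
                cell_id=0,
                area=area_px * spec.pixel_size**2,
                perimeter=2 * np.pi * r * spec.pixel_size,
                circularity=1.0,
                roundness=1.0,
                solidity=1.0,
                aspect_ratio=1.0,
                centroid=(py, px),
                integrated_density=float(img[disc].sum()),
                border_warning=border,
            )
        )
    true_percent = (
        100.0 * (1.0 - spec.diffuse_fraction) if total_puncta_px else 0.0
    )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return img, records, true_percent


# ---------------------------------------------------------------------------
# ThT curves and densitometry


def simulate_tht_curve(spec: ThtSpec, replicate_id: str = "r1") -> KineticTrace:
    """Logistic aggregation curve plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    with np.errstate(over="ignore"):  # steep curves saturate harmlessly
        f = spec.baseline + (spec.plateau - spec.baseline) / (
            1.0 + np.exp(-spec.steepness * (t - spec.t_half))
        )
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return KineticTrace(timestamps=t, fluorescence=f, replicate_id=replicate_id)


def simulate_densitometry(
    truth: SolubilityTruth,
    loading_normalizer: float = 1.0,
    volume_factors: tuple[float, float] = (1.0, 1.0),
) -> tuple[DensitometryRow, DensitometryRow]:
    """Soluble (S) and insoluble (P) band densities for one sample.

    Band density is the corrected abundance re-expressed on the gel
    scale: ``density = abundance × loading_normalizer / volume_factor``,
    so the percent-insoluble computation inverts the corrections and
    recovers ``percent_insoluble`` exactly at zero noise and in
    expectation otherwise.
    """
    rng = np.random.default_rng(truth.seed)
    p_frac = truth.percent_insoluble / 100.0
    s_ab = truth.total_abundance * (1.0 - p_frac)
    p_ab = truth.total_abundance * p_frac
    rows = []
    for frac, ab, vol in (("S", s_ab, volume_factors[0]), ("P", p_ab, volume_factors[1])):
        ln = loading_normalizer + (
            rng.normal(0.0, truth.loading_noise_sd) if truth.loading_noise_sd > 0 else 0.0
        )
        ln = max(ln, 1e-9)
        density = ab * ln / vol
        if truth.band_noise_sd > 0:
            density = max(0.0, density + rng.normal(0.0, truth.band_noise_sd))
        rows.append(
            DensitometryRow(
                sample_id=truth.sample_id,
                protein="",
                condition="",
                fraction=frac,
                band_density=float(density),
                loading_normalizer=float(ln),
                volume_factor=float(vol),
            )
        )
    return rows[0], rows[1]


# ---------------------------------------------------------------------------
# disk output


def write_frap_dataset(stack: ImageStack, path: str | Path, stem: str = "frap") -> dict:
    """Write a stack as 16-bit multi-page TIFF plus a JSON sidecar.

    The sidecar records timestamps, the bleach frame index, the
    stimulation ROI (as a run-length-free list of true-pixel coords kept
    compact by bounding box) and the pixel size.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pix = np.clip(stack.pixels, 0, 65535).astype(np.uint16)
    tif_path = path / f"{stem}.tif"
    tifffile.imwrite(tif_path, pix, photometric="minisblack")
    roi = stack.stimulation_roi
    sidecar = {
        "timestamps_s": stack.timestamps.tolist(),
        "bleach_frame_index": stack.bleach_frame_index,
        "pixel_size_um": stack.pixel_size,
        "stimulation_roi": (
            None if roi is None else np.argwhere(roi.mask).tolist()
        ),
        "frame_shape": list(stack.pixels.shape[1:]),
    }
    with open(path / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh)
    return sidecar


def read_frap_dataset(path: str | Path, stem: str = "frap") -> ImageStack:
    """Read a TIFF + JSON sidecar pair written by :func:`write_frap_dataset`."""
    path = Path(path)
    pix = tifffile.imread(path / f"{stem}.tif")
    with open(path / f"{stem}.json") as fh:
        sidecar = json.load(fh)
    roi = None
    if sidecar["stimulation_roi"] is not None:
        mask = np.zeros(tuple(sidecar["frame_shape"]), dtype=bool)
        coords = np.asarray(sidecar["stimulation_roi"], dtype=int)
        if coords.size:
            mask[coords[:, 0], coords[:, 1]] = True
        roi = RoiMask(mask)
    return ImageStack(
        pixels=pix.astype(float),
        timestamps=np.asarray(sidecar["timestamps_s"]),
        pixel_size=sidecar["pixel_size_um"],
        bleach_frame_index=sidecar["bleach_frame_index"],
        stimulation_roi=roi,
    )
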