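"""FRAP quantification: ROI construction, trace extraction, normalization
and single-exponential recovery fitting.

The workflow follows the standard confocal FRAP protocol for
condensates: register the stack, threshold the pre- and post-bleach
signal, form the FRAP ROI as the bleached part of the punctum
(pre-bleach mask minus post-bleach mask), extract the per-frame ratio of
integrated densities (FRAP ROI over pre-bleach ROI), anchor-normalize it
(pre-bleach mean → 1, first post-bleach value → 0), and fit the
post-bleach points to

    f(t) = A · (1 − exp(−t/τ))

where ``A`` is the mobile fraction and ``τ`` the recovery time constant.
``τ`` is conventionally reported as the "half time"; the time to reach
half of the recovered signal is actually ``τ·ln 2``, which is exposed
separately as ``t_half_ln2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .imaging import GeometryWarning, ImageStack, PunctumRecord, RoiMask


@dataclass
class FrapTrace:
    """A FRAP intensity time series.

    Timestamps are in seconds with t = 0 at the first post-bleach frame
    (pre-bleach frames have negative times). ``raw_values`` are
    integrated-density ratios; ``normalized_values`` are set by
    :func:`normalize_trace`.
    """

    timestamps: np.ndarray
    raw_values: np.ndarray
    n_prebleach: int
    normalized_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if self.timestamps.shape != self.raw_values.shape:
            raise ValueError("timestamps and values must align")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach point")
        if self.n_prebleach >= len(self.timestamps):
            raise ValueError("need at least one post-bleach point")

    @property
    def phase_labels(self) -> np.ndarray:
        labels = np.full(len(self.timestamps), "post", dtype=object)
        labels[: self.n_prebleach] = "pre"
        return labels

    @property
    def post_times(self) -> np.ndarray:
        return self.timestamps[self.n_prebleach :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.timestamps,
                "raw": self.raw_values,
                "normalized": (
                    self.normalized_values
                    if self.normalized_values is not None
                    else np.full(len(self.timestamps), np.nan)
                ),
                "phase": self.phase_labels,
            }
        )


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters."""

    mobile_fraction: float
    half_time: float  # τ of the exponential, s
    rss: float
    converged: bool
    identifiability_flag: bool = False
    group: str | None = None

    @property
    def t_half_ln2(self) -> float:
        """Time to half of the recovered signal, τ·ln 2 (seconds)."""
        return self.half_time * np.log(2.0)


# ---------------------------------------------------------------------------
# candidate selection


def select_bleach_candidates(
    records: list[PunctumRecord],
    stimulation_roi_area: float,
    exclusion_radius: float | None = None,
    size_band: tuple[float, float] | None = None,
    pixel_size: float = 1.0,
    max_bleach_fraction: float = 0.80,
) -> tuple[list[PunctumRecord], dict[int, list[str]]]:
    """Filter puncta eligible for photobleaching.

    A punctum is kept when (a) the stimulation ROI covers at most
    ``max_bleach_fraction`` (default 80%) of its area, (b) no other
    punctum centroid lies within ``exclusion_radius`` µm (default:
    twice the candidate's equivalent diameter), and (c) its area falls
    inside ``size_band`` (µm²), if given. Returns the kept records and a
    per-punctum list of rejection reasons.
    """
    kept: list[PunctumRecord] = []
    reasons: dict[int, list[str]] = {}
    centroids = np.array([r.centroid for r in records], dtype=float).reshape(-1, 2)
    for i, rec in enumerate(records):
        rej: list[str] = []
        if rec.area <= 0 or stimulation_roi_area / rec.area > max_bleach_fraction:
            rej.append("bleach_fraction")
        excl = exclusion_radius
        if excl is None:
            excl = 2.0 * 2.0 * np.sqrt(rec.area / np.pi)  # 2x equivalent diameter
        if len(records) > 1:
            d = np.hypot(
                centroids[:, 0] - centroids[i, 0], centroids[:, 1] - centroids[i, 1]
            ) * pixel_size
            d[i] = np.inf
            if np.any(d < excl):
                rej.append("neighbor")
        if size_band is not None and not (size_band[0] <= rec.area <= size_band[1]):
            rej.append("size_band")
        if rej:
            reasons[rec.punctum_id] = rej
        else:
            kept.append(rec)
    return kept, reasons


# ---------------------------------------------------------------------------
# ROI arithmetic and trace extraction


def punctum_masks_from_stack(stack: ImageStack) -> tuple[RoiMask, RoiMask]:
    """Threshold the pre- and post-bleach punctum signal of a stack.

    The pre-bleach mask is the Otsu foreground of the mean pre-bleach
    frame. The post-bleach mask is the Otsu foreground of the first
    post-bleach frame restricted to the pre-bleach mask, where the only
    two intensity populations are the bleached and the surviving
    punctum signal. Returns ``(pre_mask, post_mask)``.
    """
    from skimage.filters import threshold_otsu

    if stack.bleach_frame_index is None:
        raise ValueError("stack has no bleach event")
    pre_frame = stack.pixels[: stack.bleach_frame_index].mean(axis=0)
    post_frame = stack.pixels[stack.bleach_frame_index]
    pre_mask = RoiMask(pre_frame > threshold_otsu(pre_frame))
    within = post_frame[pre_mask.mask]
    thr = threshold_otsu(within) if np.ptp(within) > 0 else np.inf
    return pre_mask, RoiMask((post_frame > thr) & pre_mask.mask)


def build_frap_roi(prebleach_mask: RoiMask, postbleach_mask: RoiMask) -> RoiMask:
    """The bleached region: pre-bleach signal minus post-bleach signal.

    Equivalent to masking the pre-bleach ROI, inverting it, and
    subtracting the post-bleach ROI — the result is the set difference
    ``pre \\ post``. Raises if the difference is empty (no bleached
    signal); warns if the masks are disjoint (the post-bleach signal
    does not overlap the punctum at all).
    """
    if prebleach_mask.mask.shape != postbleach_mask.mask.shape:
        raise ValueError("masks must be congruent")
    diff = prebleach_mask.mask & ~postbleach_mask.mask
    if not diff.any():
        raise ValueError("no bleached signal detected (empty FRAP ROI)")
    if not (prebleach_mask.mask & postbleach_mask.mask).any():
        warnings.warn(
            "pre- and post-bleach masks are disjoint; FRAP ROI equals the "
            "pre-bleach mask",
            GeometryWarning,
        )
    return RoiMask(diff)


def extract_trace(
    stack: ImageStack,
    frap_roi: RoiMask,
    prebleach_roi: RoiMask,
    denominator: str = "reference",
) -> FrapTrace:
    """FRAP-ROI integrated density divided by pre-bleach-ROI density.

    With ``denominator="reference"`` (default) the divisor is the
    pre-bleach ROI's integrated density averaged over the pre-bleach
    frames — a constant, so the trace is an affine image of the
    underlying recovery and the downstream two-anchor normalization
    recovers the model curve exactly. ``denominator="per_frame"``
    divides by the pre-bleach ROI's density in each frame instead,
    which additionally cancels whole-frame acquisition photobleaching
    when the punctum's total intensity is conserved after the bleach.

    The stack must carry ``bleach_frame_index``; timestamps are shifted
    so that t = 0 at the first post-bleach frame.
    """
    if stack.bleach_frame_index is None:
        raise ValueError("stack has no bleach event")
    if denominator not in ("reference", "per_frame"):
        raise ValueError("denominator must be 'reference' or 'per_frame'")
    for roi in (frap_roi, prebleach_roi):
        if roi.mask.shape != stack.pixels.shape[1:]:
            raise ValueError("ROI shape must match stack frames")
    pix = stack.pixels.astype(float)
    num = pix[:, frap_roi.mask].sum(axis=1)
    den = pix[:, prebleach_roi.mask].sum(axis=1)
    if denominator == "reference":
        den = np.full_like(den, den[: stack.bleach_frame_index].mean())
    if np.any(den == 0):
        raise ValueError("zero pre-bleach-ROI integrated density")
    t0 = stack.timestamps[stack.bleach_frame_index]
    return FrapTrace(
        timestamps=stack.timestamps - t0,
        raw_values=num / den,
        n_prebleach=stack.bleach_frame_index,
    )


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Two-anchor normalization of a FRAP trace.

    The affine map ``x ↦ (x − F0) / (F̄_pre − F0)`` with ``F̄_pre`` the
    mean of the pre-bleach values and ``F0`` the first post-bleach value
    sends the pre-bleach mean to exactly 1 and the first post-bleach
    value to exactly 0. Applying it to an already-normalized trace is a
    no-op (idempotent).
    """
    values = (
        trace.normalized_values
        if trace.normalized_values is not None
        else trace.raw_values
    )
    f_pre = values[: trace.n_prebleach].mean()
    f0 = values[trace.n_prebleach]
    if f_pre == f0:
        raise ValueError("no bleach contrast: pre-bleach mean equals first post value")
    norm = (values - f0) / (f_pre - f0)
    return FrapTrace(
        timestamps=trace.timestamps,
        raw_values=trace.raw_values,
        n_prebleach=trace.n_prebleach,
        normalized_values=norm,
    )


# ---------------------------------------------------------------------------
# model fitting


def _recovery(t, a, tau):
    return a * (1.0 - np.exp(-t / tau))


def fit_recovery(
    trace: FrapTrace,
    identifiability_threshold: float = 0.02,
    max_restarts: int = 3,
) -> FrapFit:
    """Bounded least-squares fit of ``A·(1 − exp(−t/τ))``.

    Only post-bleach points enter the fit (the model describes pure
    recovery). Bounds: A ∈ [0, 1.5], τ ∈ (0, 10×last time]. Initial
    values: A₀ = mean of the last three normalized points; τ₀ = first
    time the trace crosses A₀/2 (fallback: mid-span). When the fitted
    amplitude is below ``identifiability_threshold`` the time constant
    is unconstrained by the data and the fit is flagged.
    """
    if trace.normalized_values is None:
        raise ValueError("normalize the trace before fitting")
    t = trace.post_times
    y = trace.normalized_values[trace.n_prebleach :]
    if len(t) < 4:
        raise ValueError("need at least 4 post-bleach points")

    t_max = t[-1]
    a0 = float(np.clip(np.mean(y[-3:]), 0.0, 1.5))
    crossing = np.nonzero(y >= a0 / 2.0)[0]
    tau0 = float(t[crossing[0]]) if crossing.size and t[crossing[0]] > 0 else t_max / 2.0
    tau0 = float(np.clip(tau0, 1e-6, 10.0 * t_max))

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts):
        p0 = (a0, tau0) if attempt == 0 else (
            float(rng.uniform(0.0, 1.5)),
            float(rng.uniform(1e-3, t_max)),
        )
        try:
            popt, _ = curve_fit(
                _recovery,
                t,
                y,
                p0=p0,
                bounds=([0.0, 1e-9], [1.5, 10.0 * t_max]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _recovery(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return FrapFit(
            mobile_fraction=np.nan, half_time=np.nan, rss=np.nan, converged=False
        )
    (a, tau), rss = best
    return FrapFit(
        mobile_fraction=float(a),
        half_time=float(tau),
        rss=rss,
        converged=True,
        identifiability_flag=a < identifiability_threshold,
    )


def summarize_frap(
    fits: list[FrapFit], groups: list[str] | None = None
) -> pd.DataFrame:
    """Per-group mean, SEM and n of mobile fraction and time constant.

    Non-converged fits are excluded (their count is reported). With a
    single fit in a group the SEM is undefined and reported as NaN.
    """
    if groups is None:
        groups = [f.group if f.group is not None else "all" for f in fits]
    if len(groups) != len(fits):
        raise ValueError("one group label per fit required")
    df = pd.DataFrame(
        {
            "group": groups,
            "mobile_fraction": [f.mobile_fraction for f in fits],
            "tau_s": [f.half_time for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    rows = []
    for g, sub in df.groupby("group", sort=False):
        conv = sub[sub["converged"]]
        if conv.empty:
            warnings.warn(f"group {g!r} has no converged fits; omitted", UserWarning)
            continue
        n = len(conv)
        rows.append(
            {
                "group": g,
                "n": n,
                "n_excluded": len(sub) - n,
                "mobile_fraction_mean": conv["mobile_fraction"].mean(),
                "mobile_fraction_sem": (
                    conv["mobile_fraction"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                ),
                "tau_mean_s": conv["tau_s"].mean(),
                "tau_sem_s": (
                    conv["tau_s"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
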