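"""Biochemical quantifications: solubility fractions and ThT kinetics.

Percent-insoluble protein is computed from soluble (S) and insoluble
(P) band densitometry, each band normalized to its own lane's total
protein loading and corrected by an explicit lysate-volume factor:

    % insoluble = 100 · P_corr / (S_corr + P_corr)

ThT aggregation traces are summarized by the time to half transition to
steady state: the first crossing of the midpoint between the baseline
(mean of the first 5% of points) and the plateau (mean of the last
10%), linearly interpolated. A trace qualifies as having reached steady
state when the least-squares slope over its last 10% of points is below
1% of the dynamic range per hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DensitometryRow:
    """One gel band: density plus its lane-level corrections."""

    sample_id: str
    protein: str
    condition: str
    fraction: str  # "S" (soluble) or "P" (insoluble pellet)
    band_density: float
    loading_normalizer: float  # Ponceau or GAPDH, > 0
    volume_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.fraction not in ("S", "P"):
            raise ValueError("fraction must be 'S' or 'P'")
        if self.band_density < 0:
            raise ValueError("band_density must be non-negative")
        if self.loading_normalizer <= 0:
            raise ValueError("loading_normalizer must be positive")
        if self.volume_factor <= 0:
            raise ValueError("volume_factor must be positive")

    @property
    def corrected_density(self) -> float:
        """Loading-normalized density scaled by the lysate-volume factor."""
        return self.band_density / self.loading_normalizer * self.volume_factor


@dataclass
class KineticTrace:
    """A plate-reader fluorescence-vs-time trace (hours, a.u.)."""

    timestamps: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.timestamps.shape != self.fluorescence.shape:
            raise ValueError("timestamps and fluorescence must align")
        if len(self.timestamps) < 3:
            raise ValueError("need at least 3 points")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ThtSummary:
    t50: float | None
    baseline: float
    plateau: float
    steady_state_reached: bool


def percent_insoluble(s_row: DensitometryRow, p_row: DensitometryRow) -> float:
    """Percent of a sample's protein in the insoluble fraction.

    100 × P_corr / (S_corr + P_corr), on loading-normalized,
    volume-corrected band densities. Invariant under any common
    rescaling of both rows' densities.
    """
    if s_row.sample_id != p_row.sample_id:
        raise ValueError("S and P rows must share a sample_id")
    if s_row.fraction != "S" or p_row.fraction != "P":
        raise ValueError("expected an (S, P) row pair")
    s_corr = s_row.corrected_density
    p_corr = p_row.corrected_density
    total = s_corr + p_corr
    if total <= 0:
        raise ValueError("corrected S + P total must be positive")
    return 100.0 * p_corr / total


def tht_t50(
    trace: KineticTrace,
    baseline_frac: float = 0.05,
    plateau_frac: float = 0.10,
    steady_slope_tol: float = 0.01,
) -> ThtSummary:
    """Time to half transition to steady state, model-free.

    Baseline = mean of the first ``baseline_frac`` of points; plateau =
    mean of the last ``plateau_frac``. t50 is the first time the trace
    crosses their midpoint, linearly interpolated between the bracketing
    samples. If the final-window slope exceeds ``steady_slope_tol`` of
    the dynamic range per hour the steady state has not been reached and
    t50 is withheld.
    """
    t = trace.timestamps
    f = trace.fluorescence
    n = len(t)
    n_base = max(1, int(np.ceil(baseline_frac * n)))
    n_plat = max(2, int(np.ceil(plateau_frac * n)))
    baseline = float(f[:n_base].mean())
    plateau = float(f[-n_plat:].mean())
    if plateau <= baseline:
        raise ValueError("no transition: plateau does not exceed baseline")

    span = plateau - baseline
    slope = np.polyfit(t[-n_plat:], f[-n_plat:], 1)[0]
    if abs(slope) > steady_slope_tol * span:
        return ThtSummary(
            t50=None, baseline=baseline, plateau=plateau, steady_state_reached=False
        )

    half = baseline + span / 2.0
    above = f >= half
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise ValueError("trace never crosses the half-transition level")
    i = idx[0]
    if i == 0:
        t50 = float(t[0])
    else:
        t50 = float(
            t[i - 1] + (half - f[i - 1]) / (f[i] - f[i - 1]) * (t[i] - t[i - 1])
        )
    return ThtSummary(
        t50=t50, baseline=baseline, plateau=plateau, steady_state_reached=True
    )


def tht_t50_logistic(trace: KineticTrace) -> float:
    """Cross-check estimator: t50 from a four-parameter logistic fit."""
    from scipy.optimize import curve_fit

    t, f = trace.timestamps, trace.fluorescence

    def logistic(t, lo, hi, t50, k):
        return lo + (hi - lo) / (1.0 + np.exp(-k * (t - t50)))

    span = np.ptp(f)
    p0 = (float(f[:3].mean()), float(f[-3:].mean()), float(t[np.argmin(np.abs(f - f.min() - span / 2))]), 1.0)
    popt, _ = curve_fit(logistic, t, f, p0=p0, maxfev=10000)
    return float(popt[2])


def average_replicates(traces: list[KineticTrace]) -> tuple[KineticTrace, np.ndarray]:
    """Pointwise mean trace and SEM across replicates.

    Requires a common time grid. With a single replicate the SEM is
    undefined (NaN) and a warning is issued.
    """
    if not traces:
        raise ValueError("no traces given")
    t0 = traces[0].timestamps
    for tr in traces[1:]:
        if not np.array_equal(tr.timestamps, t0):
            raise ValueError("replicates must share a common time grid")
    stack = np.vstack([tr.fluorescence for tr in traces])
    mean = stack.mean(axis=0)
    if len(traces) == 1:
        warnings.warn("single replicate: SEM undefined", UserWarning)
        sem = np.full_like(mean, np.nan)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(traces))
    return KineticTrace(timestamps=t0, fluorescence=mean, replicate_id="mean"), sem
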