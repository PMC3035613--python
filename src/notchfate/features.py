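"""Limit-cycle feature extraction and cell-fate classification.

The analysis reasons with a handful of qualitative trajectory features:
oscillation period (mean inter-peak interval), amplitude relative to the
mean level, interleaving of Mash1 peaks between Hes1 peaks (antiphase),
the lag until the system returns to its baseline resting state after a
perturbation, and a categorical fate label.

Fate rule (thresholds are configurable; the biology is verbal —
"dampened oscillations", "significantly small Hes1" — so the defaults
quantify it):

* ``differentiated``       — both Hes1 and Mash1 relative amplitudes are
  below ``eps_amp`` (non-oscillatory), mean Mash1 exceeds mean Hes1, and
  mean Hes1 has fallen below ``theta_low`` times its baseline mean;
* ``oscillatory_progenitor`` — a sustained, regular oscillation
  (period defined, period CV < 0.2, relative amplitude >= ``eps_amp``)
  with Hes1 dominance (mean Hes1 > mean Mash1);
* ``dampened_transition``  — amplitudes still above the floor but
  declining between the two halves of the window;
* ``other``                — anything else.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .simulation import Trajectory

__all__ = [
    "OscillationFeatures",
    "FateLabel",
    "detect_peaks",
    "oscillation_features",
    "antiphase_check",
    "classify_fate",
    "return_to_rest_lag",
    "phase_plane",
]

#: relative amplitude below this fraction of the mean counts as
#: non-oscillatory (the "dampened-out" floor)
EPS_AMP = 0.05
#: "significantly small" Hes1: mean below this fraction of baseline
THETA_LOW = 0.5
#: default peak prominence, as a fraction of the series range
PROMINENCE = 0.1
#: period CV above this is not a regular oscillation
PERIOD_CV_MAX = 0.2
#: relative amplitude must drop by at least this factor between window
#: halves to count as "declining"
DECLINE_FACTOR = 0.9


class FateLabel(str, enum.Enum):
    oscillatory_progenitor = "oscillatory_progenitor"
    dampened_transition = "dampened_transition"
    differentiated = "differentiated"
    other = "other"


@dataclass(frozen=True)
class OscillationFeatures:
    period: float  # min; NaN when undefined (< 3 peaks)
    period_cv: float
    amplitude: float  # mean peak-to-trough
    mean_level: float
    relative_amplitude: float
    peak_times: tuple[float, ...] = field(default=())
    flagged: bool = False  # True when too few peaks for a period

    @property
    def period_defined(self) -> bool:
        return math.isfinite(self.period)

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "period_cv": self.period_cv,
            "amplitude": self.amplitude,
            "mean_level": self.mean_level,
            "relative_amplitude": self.relative_amplitude,
            "peak_times": list(self.peak_times),
            "flagged": self.flagged,
        }


def detect_peaks(
    times: np.ndarray, series: np.ndarray, min_prominence: float = PROMINENCE
) -> np.ndarray:
    """Times of local maxima with prominence >= min_prominence * range."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if series.size < 10:
        raise ValueError("series too short for peak detection (need >= 10 samples)")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    rng = float(series.max() - series.min())
    if rng == 0.0:
        return np.empty(0)
    idx, _ = find_peaks(series, prominence=min_prominence * rng)
    return times[idx]


def _matched_amplitude(times, series, peak_times) -> float:
    """Mean peak-to-trough amplitude from troughs between adjacent peaks."""
    if len(peak_times) < 2:
        return float(series.max() - series.min())
    amps = []
    for t0, t1 in zip(peak_times[:-1], peak_times[1:]):
        m = (times >= t0) & (times <= t1)
        seg = series[m]
        peak = 0.5 * (seg[0] + seg[-1])
        amps.append(peak - seg.min())
    return float(np.mean(amps))


def oscillation_features(
    traj: Trajectory,
    species: str,
    window: tuple[float, float] | None = None,
    min_prominence: float = PROMINENCE,
) -> OscillationFeatures:
    """Period / amplitude / mean-level summary of one species in a window.

    With fewer than 3 peaks the period is NaN and the result is flagged.
    """
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    w = traj.window(*window)
    series = w.column(species)
    peaks = detect_peaks(w.times, series, min_prominence)
    mean_level = float(series.mean())
    amplitude = _matched_amplitude(w.times, series, peaks)
    if len(peaks) >= 3:
        intervals = np.diff(peaks)
        period = float(intervals.mean())
        period_cv = float(intervals.std() / intervals.mean())
        flagged = False
    else:
        period, period_cv, flagged = math.nan, math.nan, True
        amplitude = float(series.max() - series.min()) / 2.0
    rel = amplitude / mean_level if mean_level > 0 else 0.0
    return OscillationFeatures(
        period=period,
        period_cv=period_cv,
        amplitude=amplitude,
        mean_level=mean_level,
        relative_amplitude=rel,
        peak_times=tuple(peaks.tolist()),
        flagged=flagged,
    )


def antiphase_check(
    traj: Trajectory,
    species_a: str = "hes1_prot_nuc",
    species_b: str = "mash1_prot_nuc",
    window: tuple[float, float] | None = None,
    min_prominence: float = PROMINENCE,
) -> tuple[bool | None, list[float]]:
    """Do the peaks of ``species_b`` interleave those of ``species_a``?

    True iff every full inter-peak interval of ``species_a`` inside the
    window contains exactly one ``species_b`` peak, strictly inside it
    (more than one grid step away from either edge).  Returns the
    fractional phase offsets of the interleaved peaks; ``(None, [])``
    when either species lacks 3 peaks (indeterminate).
    """
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    w = traj.window(*window)
    pa = detect_peaks(w.times, w.column(species_a), min_prominence)
    pb = detect_peaks(w.times, w.column(species_b), min_prominence)
    if len(pa) < 3 or len(pb) < 3:
        return None, []
    tol = w.step
    offsets: list[float] = []
    ok = True
    for t0, t1 in zip(pa[:-1], pa[1:]):
        inside = pb[(pb > t0 + tol) & (pb < t1 - tol)]
        if inside.size != 1:
            ok = False
            continue
        offsets.append(float((inside[0] - t0) / (t1 - t0)))
    return ok, offsets


def classify_fate(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    baseline_hes1_mean: float | None = None,
    eps_amp: float = EPS_AMP,
    theta_low: float = THETA_LOW,
) -> FateLabel:
    """Categorical fate of the trajectory over ``window``.

    ``baseline_hes1_mean`` is the unperturbed limit-cycle mean of nuclear
    Hes1 protein; without it the "Hes1 below half baseline" clause of the
    differentiated rule is skipped.
    """
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    hes1 = oscillation_features(traj, prot_nuc_name("hes1"), window)
    mash1 = oscillation_features(traj, prot_nuc_name("mash1"), window)

    hes1_low = (
        True
        if baseline_hes1_mean is None
        else hes1.mean_level < theta_low * baseline_hes1_mean
    )
    if (
        hes1.relative_amplitude < eps_amp
        and mash1.relative_amplitude < eps_amp
        and mash1.mean_level > hes1.mean_level
        and hes1_low
    ):
        return FateLabel.differentiated
    if (
        hes1.period_defined
        and hes1.period_cv < PERIOD_CV_MAX
        and hes1.relative_amplitude >= eps_amp
        and hes1.mean_level > mash1.mean_level
    ):
        return FateLabel.oscillatory_progenitor

    # declining amplitudes between the two halves of the window?
    t0, t1 = window
    mid = 0.5 * (t0 + t1)
    declining = True
    for species in ("hes1", "mash1"):
        first = oscillation_features(traj, prot_nuc_name(species), (t0, mid))
        second = oscillation_features(traj, prot_nuc_name(species), (mid, t1))
        if not second.relative_amplitude < DECLINE_FACTOR * first.relative_amplitude:
            declining = False
    if declining:
        return FateLabel.dampened_transition
    return FateLabel.other


def prot_nuc_name(gene: str) -> str:
    return f"{gene}_prot_nuc"


def return_to_rest_lag(
    traj: Trajectory,
    baseline: OscillationFeatures,
    protocol_end: float,
    species: str = "mash1_prot_nuc",
    window_length: float = 600.0,
    stride: float = 30.0,
    period_tol: float = 0.05,
    mean_tol: float = 0.10,
) -> float:
    """Minutes after ``protocol_end`` until a sliding window of the
    trajectory matches the baseline features (period within
    ``period_tol``, mean within ``mean_tol``).  ``inf`` if never matched;
    0 when the protocol is empty (nothing to recover from)."""
    if traj.protocol.is_empty and protocol_end <= traj.times[0]:
        return 0.0
    t_max = float(traj.times[-1])
    start = protocol_end
    while start + window_length <= t_max + 1e-9:
        f = oscillation_features(traj, species, (start, start + window_length))
        if (
            f.period_defined
            and baseline.period_defined
            and abs(f.period - baseline.period) <= period_tol * baseline.period
            and abs(f.mean_level - baseline.mean_level) <= mean_tol * baseline.mean_level
        ):
            return float(start - protocol_end)
        start += stride
    return math.inf


def phase_plane(
    traj: Trajectory,
    species_mrna: str,
    species_protein: str,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, bool]:
    """(mRNA, protein) point sequence over the window plus a closed-loop
    flag: True when the window still traces a (near-)closed periodic
    orbit, False for a contracting spiral or a fixed point."""
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    w = traj.window(*window)
    pts = np.column_stack([w.column(species_mrna), w.column(species_protein)])
    f = oscillation_features(traj, species_protein, window)
    closed = bool(f.period_defined and f.relative_amplitude >= EPS_AMP)
    if closed:
        # orbit closure: the end point must come back near the orbit's
        # earlier turns (within 10% of the point-cloud scale)
        scale = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        if scale > 0 and f.period_defined:
            n_back = int(round(f.period / w.step))
            if n_back and n_back < len(pts):
                gap = np.linalg.norm(pts[-1] - pts[-1 - n_back])
                closed = bool(gap < 0.1 * scale)
    return pts, closed
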