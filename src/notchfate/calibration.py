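"""Qualitative-cost calibration: Sobol scan of the parameter hypercube.

No quantitative time-series data exist for the pathway, so parameters
are scored against qualitative features of the observed biology: a
sustained oscillation with a ~2 h period, Hes1 dominance over Mash1, and
Mash1 peaks interleaving Hes1 peaks.  The cost is a sum of non-negative
penalty terms evaluated over the last 1,000 min of a 3,000 min run
(resting-state window); the search evaluates it on a Sobol low-
discrepancy sequence over the 31-parameter hypercube (centre values
+/- 90%) and returns the argmin together with the running-minimum
convergence record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .features import antiphase_check, oscillation_features
from .parameters import ParameterSet, ParameterSpace
from .simulation import IntegrationError, SolverOptions, Trajectory, integrate
from .wiring import Wiring, default_wiring

__all__ = [
    "CostSettings",
    "CostBreakdown",
    "CalibrationResult",
    "qualitative_cost",
    "sobol_points",
    "calibrate",
]

log = logging.getLogger(__name__)

#: cost assigned to invalid (failed / non-finite / negative) simulations
VALIDITY_PENALTY = 100.0


@dataclass(frozen=True)
class CostSettings:
    """Targets and weights of the qualitative cost terms."""

    target_period: float = 120.0  # min; the reported ~2 h oscillation
    eps_osc: float = 0.05  # sustained-oscillation floor (relative amplitude)
    window: float = 1000.0  # evaluation window, trailing, min
    horizon: float = 3000.0  # simulation length, min
    weights: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CostBreakdown:
    """Total qualitative cost and its named non-negative terms."""

    terms: dict[str, float]
    window: tuple[float, float]

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    def to_dict(self) -> dict:
        return {"total": self.total, "terms": dict(self.terms), "window": list(self.window)}


def qualitative_cost(
    traj: Trajectory | None,
    settings: CostSettings | None = None,
) -> CostBreakdown:
    """Score a trajectory against the qualitative features.

    Terms (all >= 0, 0 = feature matched):

    1. sustained-oscillation: shortfall of the Hes1 relative amplitude
       below ``eps_osc``, as a fraction of ``eps_osc``;
    2. period: ``|period - target| / target`` (1 when undefined);
    3. dominance: positive part of (mean Mash1 - mean Hes1), normalised
       by the sum of the means;
    4. antiphase: fraction of Hes1 inter-peak intervals not containing
       exactly one Mash1 peak (1 when indeterminate);
    5. validity: large constant when the trajectory is missing/invalid.

    ``traj=None`` (failed integration) yields only the validity penalty.
    """
    s = settings or CostSettings()
    w = s.weights
    if traj is None:
        return CostBreakdown(
            terms={
                "oscillation": 0.0,
                "period": 0.0,
                "dominance": 0.0,
                "antiphase": 0.0,
                "validity": w[4] * VALIDITY_PENALTY,
            },
            window=(float("nan"), float("nan")),
        )
    t_end = float(traj.times[-1])
    window = (t_end - s.window, t_end)
    hes1 = oscillation_features(traj, "hes1_prot_nuc", window)
    mash1 = oscillation_features(traj, "mash1_prot_nuc", window)

    osc = max(0.0, (s.eps_osc - hes1.relative_amplitude) / s.eps_osc)
    if hes1.period_defined:
        period = abs(hes1.period - s.target_period) / s.target_period
    else:
        period = 1.0
    denom = hes1.mean_level + mash1.mean_level
    dominance = max(0.0, mash1.mean_level - hes1.mean_level) / denom if denom > 0 else 0.0
    ok, offsets = antiphase_check(traj, window=window)
    if ok is None:
        antiphase = 1.0
    else:
        n_intervals = max(len(hes1.peak_times) - 1, 1)
        antiphase = 1.0 - len(offsets) / n_intervals
    return CostBreakdown(
        terms={
            "oscillation": w[0] * osc,
            "period": w[1] * period,
            "dominance": w[2] * dominance,
            "antiphase": w[3] * antiphase,
            "validity": 0.0,
        },
        window=window,
    )


def sobol_points(space: ParameterSpace, m: int, skip: int = 1) -> np.ndarray:
    """``2**m`` Sobol points mapped to the hypercube, deterministically.

    ``skip`` discards the leading points of the (unscrambled) sequence;
    the default drops the degenerate all-zeros first point.  A contiguous
    block is taken so the low-discrepancy structure is preserved.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    eng = qmc.Sobol(d=space.dimension, scramble=False)
    if skip:
        eng.fast_forward(skip)
    u = eng.random(2**m)
    return space.from_unit(u)


@dataclass
class CalibrationResult:
    """Outcome of the Sobol scan, statsmodels-results style."""

    space: ParameterSpace
    best_params: ParameterSet
    best_cost: float
    best_index: int
    running_min: np.ndarray  # running minimum of the cost, per evaluation
    table: pd.DataFrame  # coordinates + per-term costs + total, per point
    settings: CostSettings = field(default_factory=CostSettings)

    @property
    def n_evaluations(self) -> int:
        return len(self.running_min)

    def summary(self) -> str:
        lines = [
            "Qualitative-cost Sobol calibration",
            f"  points evaluated : {self.n_evaluations}",
            f"  best cost        : {self.best_cost:.6f} (point {self.best_index})",
            f"  final running min: {self.running_min[-1]:.6f}",
            "  best parameters  :",
        ]
        for name in self.space.names:
            lines.append(f"    {name:14s} {self.best_params[name]:.6g}")
        return "\n".join(lines)


def calibrate(
    space: ParameterSpace,
    m: int = 10,
    skip: int = 1,
    settings: CostSettings | None = None,
    wiring: Wiring | None = None,
    options: SolverOptions | None = None,
) -> CalibrationResult:
    """Evaluate the qualitative cost on ``2**m`` Sobol points and return
    the argmin with the convergence record.

    Individual simulation failures are scored with the validity penalty
    and the scan continues; the running minimum is non-increasing by
    construction.
    """
    settings = settings or CostSettings()
    wiring = wiring or default_wiring()
    points = sobol_points(space, m=m, skip=skip)
    totals = np.empty(len(points))
    rows = []
    best_cost, best_index = math.inf, -1
    for i, x in enumerate(points):
        params = space.parameter_set(x)
        try:
            traj = integrate(
                params,
                settings.horizon,
                wiring=wiring,
                options=options,
                output_window=(settings.horizon - settings.window, settings.horizon),
            )
            cb = qualitative_cost(traj, settings)
        except IntegrationError as err:
            log.warning("simulation failed at point %d: %s", i, err)
            cb = qualitative_cost(None, settings)
        totals[i] = cb.total
        rows.append({**dict(zip(space.names, x)), **cb.terms, "total": cb.total})
        if cb.total < best_cost:
            best_cost, best_index = cb.total, i
    running_min = np.minimum.accumulate(totals)
    return CalibrationResult(
        space=space,
        best_params=space.parameter_set(points[best_index]),
        best_cost=float(best_cost),
        best_index=int(best_index),
        running_min=running_min,
        table=pd.DataFrame(rows),
        settings=settings,
    )
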