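"""In silico experiment batteries probing the self-renewal/differentiation
switch: delta-signal windows, species pulses, and single/paired tenfold
parameter ramps of the sensitivity-significant parameters.

Conventions shared by all batteries (configurable per call):

* baseline = unperturbed 3,000 min run, features over the last 1,000 min;
* ramps run linearly over (1,000, 2,000) min and hold the final value;
  outcomes are classified over (5,000, 6,000) min of a 6,000 min run;
* in ramp experiments a delta signal, when present, is held on for the
  whole run (the contrast is presence vs absence, not a window);
* pulses add a constant source to the target's cytoplasmic protein for
  980 min starting from the settled limit cycle at 3,000 min, with the
  x1 reference rate equal to the baseline time-averaged production rate
  of that protein.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .features import (
    FateLabel,
    OscillationFeatures,
    classify_fate,
    oscillation_features,
    return_to_rest_lag,
)
from .model import DeltaNotchModel
from .protocols import Protocol, Pulse, Ramp
from .simulation import Trajectory, reference_generation_rate
from .species import mrna_cyt, mrna_nuc, prot_nuc

__all__ = [
    "SCAN_DIRECTIONS",
    "Baseline",
    "ExperimentOutcome",
    "run_baseline",
    "delta_duration_battery",
    "pulse_battery",
    "single_parameter_scan",
    "pair_scan",
]

log = logging.getLogger(__name__)

#: the sensitivity-significant degradation/dissociation rates and their
#: ramp directions (x10 up for the Hes1 chain, /10 down for the
#: Mash1/Hes6 branch, i.e. stabilisation/over-expression)
SCAN_DIRECTIONS: dict[str, float] = {
    "k_d,HRN": 10.0,
    "k_d,MRN": 0.1,
    "k_d,HES1": 10.0,
    "k_d,H6RN": 0.1,
    "k_d,[M-E47]": 0.1,
}

RAMP_WINDOW = (1000.0, 2000.0)
SCAN_HORIZON = 6000.0
SCAN_WINDOW = (5000.0, 6000.0)
BASELINE_HORIZON = 3000.0
BASELINE_WINDOW = (2000.0, 3000.0)


@dataclass(frozen=True)
class Baseline:
    """Features of the unperturbed limit cycle, shared by all batteries."""

    hes1: OscillationFeatures
    mash1: OscillationFeatures
    mash1_mrna_nuc: float
    mash1_mrna_cyt: float
    trajectory: Trajectory


@dataclass
class ExperimentOutcome:
    experiment_id: str
    protocol: Protocol
    fate: FateLabel
    hes1_mean: float
    mash1_mean: float
    hes1_relamp: float
    mash1_relamp: float
    hes1_fold: float
    mash1_fold: float
    lag: float | None = None
    max_nicd: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "protocol": self.protocol.to_dict(),
            "fate": self.fate.value,
            "hes1_mean": self.hes1_mean,
            "mash1_mean": self.mash1_mean,
            "hes1_relamp": self.hes1_relamp,
            "mash1_relamp": self.mash1_relamp,
            "hes1_fold": self.hes1_fold,
            "mash1_fold": self.mash1_fold,
            "lag": self.lag,
            "max_nicd": self.max_nicd,
            **({"extra": self.extra} if self.extra else {}),
        }


def run_baseline(model: DeltaNotchModel) -> Baseline:
    traj = model.simulate(BASELINE_HORIZON)
    w = traj.window(*BASELINE_WINDOW)
    return Baseline(
        hes1=oscillation_features(traj, "hes1_prot_nuc", BASELINE_WINDOW),
        mash1=oscillation_features(traj, "mash1_prot_nuc", BASELINE_WINDOW),
        mash1_mrna_nuc=float(w.states[:, mrna_nuc("mash1")].mean()),
        mash1_mrna_cyt=float(w.states[:, mrna_cyt("mash1")].mean()),
        trajectory=traj,
    )


def _outcome(
    experiment_id: str,
    traj: Trajectory,
    window: tuple[float, float],
    baseline: Baseline,
    **kwargs,
) -> ExperimentOutcome:
    fh = oscillation_features(traj, "hes1_prot_nuc", window)
    fm = oscillation_features(traj, "mash1_prot_nuc", window)
    return ExperimentOutcome(
        experiment_id=experiment_id,
        protocol=traj.protocol,
        fate=classify_fate(traj, window, baseline_hes1_mean=baseline.hes1.mean_level),
        hes1_mean=fh.mean_level,
        mash1_mean=fm.mean_level,
        hes1_relamp=fh.relative_amplitude,
        mash1_relamp=fm.relative_amplitude,
        hes1_fold=fh.mean_level / baseline.hes1.mean_level,
        mash1_fold=fm.mean_level / baseline.mash1.mean_level,
        **kwargs,
    )


def delta_duration_battery(
    model: DeltaNotchModel,
    durations: tuple[float, ...] = (120.0, 240.0, 480.0),
    baseline: Baseline | None = None,
    start: float = 3000.0,
    recovery: float = 3000.0,
) -> list[ExperimentOutcome]:
    """Apply a delta signal of each duration to the settled limit cycle
    and record Mash1 suppression, the maximal NICD concentration and the
    recovery lag to the baseline resting state."""
    baseline = baseline or run_baseline(model)
    outcomes = []
    for dur in durations:
        if dur <= 0:
            raise ValueError("durations must be positive")
        proto = Protocol(delta_window=(start, start + dur))
        t_end = start + dur + recovery
        traj = model.simulate(t_end, protocol=proto)
        nicd = traj.column("nicd_cyt") + traj.column("nicd_nuc")
        during = traj.window(start, start + dur)
        out = _outcome(
            f"delta_{int(dur)}min",
            traj,
            (t_end - 1000.0, t_end),
            baseline,
            lag=return_to_rest_lag(traj, baseline.mash1, start + dur),
            max_nicd=float(nicd.max()),
        )
        out.extra["mash1_mean_during"] = float(
            during.states[:, prot_nuc("mash1")].mean()
        )
        out.extra["hes1_max_during"] = float(during.states[:, prot_nuc("hes1")].max())
        outcomes.append(out)
    return outcomes


def pulse_battery(
    model: DeltaNotchModel,
    genes: tuple[str, ...] = ("hes1", "mash1", "hes6"),
    magnitudes: tuple[float, ...] = (1.0, 5.0, 10.0),
    duration: float = 980.0,
    baseline: Baseline | None = None,
    start: float = 3000.0,
    recovery: float = 3000.0,
) -> list[ExperimentOutcome]:
    """Constant-generation pulses on cytoplasmic Hes1/Mash1/Hes6 for a
    fixed duration; the post-pulse window tests return to the original
    oscillatory resting state."""
    baseline = baseline or run_baseline(model)
    rates = {
        g: reference_generation_rate(
            model.params, g, wiring=model.wiring, options=model.options
        )
        for g in genes
    }
    outcomes = []
    for gene in genes:
        for mag in magnitudes:
            proto = Protocol(
                pulses=(Pulse(gene, mag, (start, start + duration), rate=rates[gene]),)
            )
            t_end = start + duration + recovery
            traj = model.simulate(t_end, protocol=proto)
            during = traj.window(start, start + duration)
            out = _outcome(
                f"pulse_{gene}_x{int(mag)}",
                traj,
                (t_end - 1000.0, t_end),
                baseline,
            )
            out.extra["hes1_mean_during"] = float(
                during.states[:, prot_nuc("hes1")].mean()
            )
            out.extra["reference_rate"] = rates[gene]
            outcomes.append(out)
    return outcomes


def _ramp_protocol(model, names_factors, delp: bool) -> Protocol:
    ramps = tuple(
        Ramp(name, model.params[name], model.params[name] * factor, RAMP_WINDOW)
        for name, factor in names_factors
    )
    return Protocol(
        ramps=ramps, delta_window=(0.0, SCAN_HORIZON) if delp else None
    )


def single_parameter_scan(
    model: DeltaNotchModel,
    directions: dict[str, float] | None = None,
    baseline: Baseline | None = None,
) -> list[ExperimentOutcome]:
    """Ramp each significant parameter tenfold in its stated direction,
    with and without a sustained delta signal, and classify the endpoint."""
    directions = directions or SCAN_DIRECTIONS
    baseline = baseline or run_baseline(model)
    outcomes = []
    for name, factor in directions.items():
        for delp in (False, True):
            proto = _ramp_protocol(model, [(name, factor)], delp)
            traj = model.simulate(SCAN_HORIZON, protocol=proto)
            out = _outcome(
                f"scan_{name}_x{factor:g}_delp{int(delp)}",
                traj,
                SCAN_WINDOW,
                baseline,
            )
            out.extra.update({"parameter": name, "factor": factor, "delp": int(delp)})
            w = traj.window(*SCAN_WINDOW)
            out.extra["mash1_mrna_nuc_fold"] = float(
                w.states[:, mrna_nuc("mash1")].mean() / baseline.mash1_mrna_nuc
            )
            out.extra["mash1_mrna_total_fold"] = float(
                (w.states[:, mrna_nuc("mash1")] + w.states[:, mrna_cyt("mash1")]).mean()
                / (baseline.mash1_mrna_nuc + baseline.mash1_mrna_cyt)
            )
            outcomes.append(out)
    return outcomes


def pair_scan(
    model: DeltaNotchModel,
    directions: dict[str, float] | None = None,
    baseline: Baseline | None = None,
) -> tuple[list[ExperimentOutcome], dict[int, list[tuple[str, str]]]]:
    """Ramp all unordered pairs of the significant parameters
    simultaneously, with and without delta; returns the outcomes and the
    differentiation-achieving pair sets keyed by delta state (0/1)."""
    directions = directions or SCAN_DIRECTIONS
    baseline = baseline or run_baseline(model)
    outcomes = []
    potent: dict[int, list[tuple[str, str]]] = {0: [], 1: []}
    for (n1, f1), (n2, f2) in itertools.combinations(directions.items(), 2):
        for delp in (False, True):
            proto = _ramp_protocol(model, [(n1, f1), (n2, f2)], delp)
            traj = model.simulate(SCAN_HORIZON, protocol=proto)
            out = _outcome(
                f"pair_{n1}+{n2}_delp{int(delp)}",
                traj,
                SCAN_WINDOW,
                baseline,
            )
            out.extra.update({"pair": [n1, n2], "delp": int(delp)})
            outcomes.append(out)
            if out.fate is FateLabel.differentiated:
                potent[int(delp)].append((n1, n2))
    return outcomes, potent
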