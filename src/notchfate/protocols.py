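"""Time-dependent experiment protocols: delta windows, pulses, ramps.

A :class:`Protocol` modifies the autonomous ODE system in three ways:

* ``delta_window`` — the binary delta signal ``delp(t)`` is 1 inside the
  window and 0 outside (``None`` means always off);
* ``pulses`` — a constant generation term added to the cytoplasmic
  protein pool of a target gene while the pulse window is active, sized
  as a multiple of a reference generation rate;
* ``ramps`` — a named parameter varied linearly from ``v0`` to ``v1``
  across a window, holding ``v1`` afterwards.

Integration is segmented at every window boundary so the discontinuities
never straddle a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .parameters import PARAM_INDEX, ParameterSet
from .species import GENES, prot_cyt

__all__ = ["Pulse", "Ramp", "Protocol"]


def _check_window(window: tuple[float, float]) -> tuple[float, float]:
    start, end = float(window[0]), float(window[1])
    if not start < end:
        raise ValueError(f"window must satisfy start < end, got {(start, end)}")
    if start < 0:
        raise ValueError("window start must be >= 0")
    return (start, end)


@dataclass(frozen=True)
class Pulse:
    """Constant source on a cytoplasmic protein pool.

    ``magnitude`` scales a reference generation rate (by default the
    baseline time-averaged production rate of the target protein, see
    :func:`notchfate.simulation.reference_generation_rate`); ``rate``
    may be given instead to use an absolute rate in concentration/min.
    """

    gene: str
    magnitude: float
    window: tuple[float, float]
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}")
        if self.magnitude < 0:
            raise ValueError("pulse magnitude must be >= 0")
        object.__setattr__(self, "window", _check_window(self.window))

    @property
    def species_index(self) -> int:
        return prot_cyt(self.gene)


@dataclass(frozen=True)
class Ramp:
    """Linear variation of one parameter over a window, held afterwards."""

    parameter: str
    v0: float
    v1: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_INDEX:
            raise ValueError(f"ramp names unknown parameter {self.parameter!r}")
        object.__setattr__(self, "window", _check_window(self.window))

    def value_at(self, t: float) -> float:
        t0, t1 = self.window
        if t <= t0:
            return self.v0
        if t >= t1:
            return self.v1
        return self.v0 + (self.v1 - self.v0) * (t - t0) / (t1 - t0)


@dataclass(frozen=True)
class Protocol:
    delta_window: tuple[float, float] | None = None
    pulses: tuple[Pulse, ...] = ()
    ramps: tuple[Ramp, ...] = ()

    def __post_init__(self) -> None:
        if self.delta_window is not None:
            object.__setattr__(self, "delta_window", _check_window(self.delta_window))
        object.__setattr__(self, "pulses", tuple(self.pulses))
        object.__setattr__(self, "ramps", tuple(self.ramps))
        names = [r.parameter for r in self.ramps]
        if len(names) != len(set(names)):
            raise ValueError("at most one ramp per parameter")

    @property
    def is_empty(self) -> bool:
        return self.delta_window is None and not self.pulses and not self.ramps

    def boundaries(self, t_end: float) -> list[float]:
        """All protocol discontinuity times inside (0, t_end)."""
        pts: set[float] = set()
        if self.delta_window:
            pts.update(self.delta_window)
        for p in self.pulses:
            pts.update(p.window)
        for r in self.ramps:
            pts.update(r.window)
        return sorted(t for t in pts if 0.0 < t < t_end)

    def delp(self, t: float) -> float:
        """Binary delta indicator at time t (1 inside the window)."""
        if self.delta_window is None:
            return 0.0
        s, e = self.delta_window
        return 1.0 if s <= t < e else 0.0

    def resolve(
        self, t: float, params: ParameterSet
    ) -> tuple[float, list[tuple[int, float]], dict[str, float]]:
        """Effective (delp, active pulse sources, ramped parameter values)
        at time ``t``.  Pulse sources are ``(species_index, rate)`` pairs;
        pulses without an absolute ``rate`` must have been resolved first
        (see ``with_pulse_rates``).
        """
        sources: list[tuple[int, float]] = []
        for p in self.pulses:
            s, e = p.window
            if s <= t < e:
                if p.rate is None:
                    raise ValueError(
                        "pulse has no absolute rate; resolve magnitudes against"
                        " a reference generation rate first"
                    )
                sources.append((p.species_index, p.magnitude * p.rate))
        ramped = {r.parameter: r.value_at(t) for r in self.ramps}
        return self.delp(t), sources, ramped

    def with_pulse_rates(self, rates: Mapping[str, float]) -> "Protocol":
        """Fill in absolute reference rates (per gene) for magnitude-scaled
        pulses that do not carry one."""
        new = tuple(
            Pulse(p.gene, p.magnitude, p.window, rate=rates[p.gene])
            if p.rate is None
            else p
            for p in self.pulses
        )
        return Protocol(self.delta_window, new, self.ramps)

    # ---- serialisation (protocol echo) ----

    def to_dict(self) -> dict:
        return {
            "delta_window": list(self.delta_window) if self.delta_window else None,
            "pulses": [
                {
                    "gene": p.gene,
                    "magnitude": p.magnitude,
                    "window": list(p.window),
                    "rate": p.rate,
                }
                for p in self.pulses
            ],
            "ramps": [
                {
                    "parameter": r.parameter,
                    "v0": r.v0,
                    "v1": r.v1,
                    "window": list(r.window),
                }
                for r in self.ramps
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Protocol":
        return cls(
            delta_window=tuple(doc["delta_window"]) if doc.get("delta_window") else None,
            pulses=tuple(
                Pulse(p["gene"], p["magnitude"], tuple(p["window"]), p.get("rate"))
                for p in doc.get("pulses", ())
            ),
            ramps=tuple(
                Ramp(r["parameter"], r["v0"], r["v1"], tuple(r["window"]))
                for r in doc.get("ramps", ())
            ),
        )
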