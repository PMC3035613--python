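"""Stiff-capable integration of the network ODEs under a protocol.

Integration is segmented at every protocol discontinuity (delta-window
and pulse edges, ramp endpoints) so the solver never steps across a
discontinuous right-hand side, and output is resampled onto a uniform
time grid (default 1 min).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._rhs import make_rhs
from .parameters import ParameterSet
from .protocols import Protocol
from .species import N_SPECIES, SPECIES, SPECIES_INDEX, mrna_cyt
from .wiring import Wiring, default_wiring

__all__ = [
    "SolverOptions",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "reference_generation_rate",
]

log = logging.getLogger(__name__)

#: default initial concentration for every component (arbitrary units)
DEFAULT_INITIAL = 0.1

#: negative excursions beyond this are an integration error; smaller ones
#: are clamped to zero (they are solver tolerance noise)
NEGATIVITY_ERROR = 1e-6
NEGATIVITY_WARN = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the solver fails; carries the last valid time/state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    step: float = 1.0  # output grid spacing, min
    max_step: float = np.inf

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rtol": self.rtol,
            "atol": self.atol,
            "step": self.step,
            "max_step": None if np.isinf(self.max_step) else self.max_step,
        }


@dataclass
class Trajectory:
    """Uniformly sampled solution: time grid x 25 named components."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 25)
    protocol: Protocol = field(default_factory=Protocol)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, N_SPECIES):
            raise ValueError(
                f"states must be (n_times, {N_SPECIES}), got {self.states.shape}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite values")

    def __len__(self) -> int:
        return self.times.size

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self) > 1 else np.nan

    def column(self, species: str) -> np.ndarray:
        return self.states[:, SPECIES_INDEX[species]]

    def window(self, start: float, end: float) -> "Trajectory":
        m = (self.times >= start - 1e-9) & (self.times <= end + 1e-9)
        if not m.any():
            raise ValueError(f"window ({start}, {end}) outside trajectory")
        return Trajectory(self.times[m], self.states[m], self.protocol, self.diagnostics)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_min", self.times)
        return df

    # ---- CSV + JSON-sidecar round trip ----

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps(
                {"protocol": self.protocol.to_dict(), "diagnostics": self.diagnostics},
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        protocol, diagnostics = Protocol(), {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            protocol = Protocol.from_dict(meta.get("protocol", {}))
            diagnostics = meta.get("diagnostics", {})
        return cls(
            df["time_min"].to_numpy(),
            df[list(SPECIES)].to_numpy(),
            protocol,
            diagnostics,
        )

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        self.to_dataframe().to_csv(buf, index=False)
        return buf.getvalue()


def _initial_state(initial) -> np.ndarray:
    if initial is None:
        return np.full(N_SPECIES, DEFAULT_INITIAL)
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (N_SPECIES,):
        raise ValueError(f"initial state must have {N_SPECIES} components")
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    return y0.copy()


def integrate(
    params: ParameterSet,
    t_end: float,
    protocol: Protocol | None = None,
    initial: np.ndarray | None = None,
    wiring: Wiring | None = None,
    options: SolverOptions | None = None,
    output_window: tuple[float, float] | None = None,
) -> Trajectory:
    """Integrate the network for ``t_end`` minutes under ``protocol``.

    ``output_window`` restricts the *recorded* grid (the integration
    always starts at t = 0); this keeps memory and resampling costs low
    for the many short-window evaluations of the sensitivity analysis.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    protocol = protocol or Protocol()
    wiring = wiring or default_wiring()
    opts = options or SolverOptions()
    y0 = _initial_state(initial)
    P = params.to_vector()

    from .parameters import PARAM_INDEX  # local to avoid polluting module ns

    ramps = [
        (PARAM_INDEX[r.parameter], r.v0, r.v1, r.window[0], r.window[1])
        for r in protocol.ramps
    ]

    grid = np.arange(0.0, t_end + opts.step / 2, opts.step)
    if output_window is not None:
        lo, hi = output_window
        grid = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
        if grid.size == 0:
            raise ValueError("output_window selects no grid points")

    seg_edges = [0.0] + protocol.boundaries(t_end) + [float(t_end)]
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    nfev = 0
    y = y0
    recorded_t0 = False
    for s0, s1 in zip(seg_edges[:-1], seg_edges[1:]):
        mid = 0.5 * (s0 + s1)
        delp, sources, _ = protocol.resolve(mid, params)
        f = make_rhs(P, wiring.arrays, delp=delp, pulses=sources, ramps=ramps)
        t_eval = grid[(grid > s0 + 1e-12) & (grid < s1 - 1e-12)]
        pieces = np.concatenate(([s0], t_eval, [s1]))
        sol = solve_ivp(
            f,
            (s0, s1),
            y,
            method=opts.method,
            t_eval=pieces,
            rtol=opts.rtol,
            atol=opts.atol,
            max_step=opts.max_step,
        )
        nfev += sol.nfev
        if not sol.success:
            raise IntegrationError(
                f"solver failed in segment ({s0}, {s1}): {sol.message}",
                t_last=float(sol.t[-1]),
                y_last=sol.y[:, -1],
            )
        y = sol.y[:, -1]
        # keep grid points; segment edges only if they are grid points
        keep = np.ones(sol.t.size, dtype=bool)
        for edge_pos in (0, sol.t.size - 1):
            on_grid = np.any(np.isclose(grid, sol.t[edge_pos], atol=1e-9))
            keep[edge_pos] = on_grid
        if recorded_t0:
            keep[0] = False  # avoid duplicating the shared edge
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep].T)
        recorded_t0 = True

    times = np.concatenate(times_out)
    states = np.vstack(states_out)

    if not np.all(np.isfinite(states)):
        bad = np.where(~np.isfinite(states))
        name = SPECIES[int(bad[1][0])]
        raise IntegrationError(
            f"non-finite value in component {name!r}", float(times[bad[0][0]]), states[-1]
        )
    m = states.min()
    if m < -NEGATIVITY_ERROR:
        i, j = np.unravel_index(states.argmin(), states.shape)
        raise IntegrationError(
            f"component {SPECIES[j]!r} went negative ({m:.3e}) at t={times[i]:.1f}",
            float(times[i]),
            states[i],
        )
    if m < 0:
        if m < -max(NEGATIVITY_WARN, 10.0 * opts.atol):
            log.warning("clamping negative excursion of %.2e to zero", m)
        states = np.clip(states, 0.0, None)

    diagnostics = {
        "nfev": int(nfev),
        "segments": len(seg_edges) - 1,
        "solver": opts.to_dict(),
    }
    return Trajectory(times, states, protocol, diagnostics)


def reference_generation_rate(
    params: ParameterSet,
    gene: str,
    wiring: Wiring | None = None,
    options: SolverOptions | None = None,
    burn_in: float = 3000.0,
    window: float = 1000.0,
) -> float:
    """Baseline time-averaged production rate of a protein: the x1 pulse
    reference, ``c_gene * <cytoplasmic mRNA>`` over the unperturbed limit
    cycle (last ``window`` min of a ``burn_in`` min run)."""
    traj = integrate(
        params,
        burn_in,
        wiring=wiring,
        options=options,
        output_window=(burn_in - window, burn_in),
    )
    mean_mrna = float(traj.states[:, mrna_cyt(gene)].mean())
    return params[f"c_{_C_KEY[gene]}"] * mean_mrna


_C_KEY = {
    "hes1": "HES1",
    "rbpj": "RBP-J",
    "notch1": "NOTCH1",
    "mash1": "MASH1",
    "hes6": "HES6",
}
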