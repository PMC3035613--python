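"""Synthetic oscillatory traces with analytic ground truth.

Damped-cosine fixtures emulating the pathway's qualitative features (a
~2 h period, Hes1 > Mash1 dominance, antiphase peak interleaving, a
damped transition, additive noise) so that feature extraction and the
qualitative cost are testable without integrating the ODE system.  The
skeleton is deliberately simpler than the model's waveforms:

    y(t) = mean + amplitude * exp(-damping * t)
                * cos(2 pi (t / period - phase)) + noise

with seeded Gaussian noise, so every expected feature value is known in
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .protocols import Protocol
from .simulation import Trajectory
from .species import N_SPECIES, SPECIES_INDEX

__all__ = ["TraceSpec", "generate_trace", "generate_paired_network_mimic"]


@dataclass(frozen=True)
class TraceSpec:
    period: float = 120.0  # min
    mean: float = 5.0
    amplitude: float = 2.0
    damping: float = 0.0  # min^-1; 0 = sustained
    phase: float = 0.0  # fraction of a period
    noise_sd: float = 0.0
    duration: float = 3000.0  # min
    step: float = 1.0  # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.duration <= 0 or self.step <= 0:
            raise ValueError("duration and step must be positive")


def generate_trace(spec: TraceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Times and values of one damped-cosine trace (seeded noise)."""
    t = np.arange(0.0, spec.duration + spec.step / 2, spec.step)
    skeleton = spec.mean + spec.amplitude * np.exp(-spec.damping * t) * np.cos(
        2 * np.pi * (t / spec.period - spec.phase)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        skeleton = skeleton + rng.normal(0.0, spec.noise_sd, size=t.size)
    return t, skeleton


def generate_paired_network_mimic(
    spec_hes1: TraceSpec,
    spec_mash1: TraceSpec | None = None,
    dominance_ratio: float = 2.0,
) -> Trajectory:
    """A Trajectory-shaped fixture with only the Hes1/Mash1 nuclear
    protein columns populated.

    By default Mash1 shares the Hes1 spec but is placed in antiphase
    (phase offset 0.5) and scaled so mean(Hes1)/mean(Mash1) equals
    ``dominance_ratio``.
    """
    if dominance_ratio <= 0:
        raise ValueError("dominance ratio must be positive")
    if spec_mash1 is None:
        spec_mash1 = replace(
            spec_hes1,
            phase=spec_hes1.phase + 0.5,
            mean=spec_hes1.mean / dominance_ratio,
            amplitude=spec_hes1.amplitude / dominance_ratio,
            seed=spec_hes1.seed + 1,
        )
    if (spec_mash1.duration, spec_mash1.step) != (spec_hes1.duration, spec_hes1.step):
        raise ValueError("both specs must share duration and step")
    t, hes1 = generate_trace(spec_hes1)
    _, mash1 = generate_trace(spec_mash1)
    scale = (spec_hes1.mean / dominance_ratio) / spec_mash1.mean
    mash1 = mash1 * scale
    states = np.zeros((t.size, N_SPECIES))
    states[:, SPECIES_INDEX["hes1_prot_nuc"]] = hes1
    states[:, SPECIES_INDEX["mash1_prot_nuc"]] = mash1
    return Trajectory(t, states, Protocol(), {"synthetic": True})
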