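"""The single-cell Delta1/Notch1 gene-network model.

Five genes (hes1, rbpj, notch1, mash1, hes6) are each described by a
two-compartment Goodwin-type chain: nuclear mRNA -> cytoplasmic mRNA ->
cytoplasmic protein -> nuclear protein, with first-order transfer and
degradation.  Transcription of gene *i* is a maximal rate ``k_i,0``
multiplied by generalised Hill repression factors (exponent ``n*h``:
``h`` binding sites, ``n`` = 2 for dimer-binding repressors), by the
NRB-complex activation term at RBPJ sites when a delta signal is
present, and by the Mash1-E47 E-box activation for the proneural genes.
Heterodimer pools (Hes1-Hes6, Mash1-E47) and the NICD/NRB branch close
the system at 25 components.

This module holds the readable, scalar implementation of every flux
(used directly by the tests and documentation); the compiled kernel in
``_rhs`` is numerically identical and is what the integrator calls.

:class:`DeltaNotchModel` is the user-facing entry point: construct it
from a parameter set (default: the calibrated optimum), then
``simulate``, ``fit`` (qualitative-cost Sobol calibration) or
``sensitivity`` (derivative-based global sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import species as sp
from .parameters import ParameterSet, ParameterSpace, table2_parameters
from .protocols import Protocol
from .simulation import SolverOptions, Trajectory, integrate
from .wiring import Wiring, default_wiring

__all__ = [
    "hill_factor",
    "transcription_rate",
    "dimer_fluxes",
    "nicd_fluxes",
    "ode_rhs",
    "DeltaNotchModel",
]

_C_KEY = {
    "hes1": "c_HES1",
    "rbpj": "c_RBP-J",
    "notch1": "c_NOTCH1",
    "mash1": "c_MASH1",
    "hes6": "c_HES6",
}
_KD_MRNA_KEY = {
    "hes1": "k_d,HRN",
    "rbpj": "k_d,RRN",
    "notch1": "k_d,NRN",
    "mash1": "k_d,MRN",
    "hes6": "k_d,H6RN",
}
_KD_PROT_KEY = {
    "hes1": "k_d,HES1",
    "rbpj": "k_d,RBP",
    "notch1": "k_d,NOTCH",
    "mash1": "k_d,MASH1",
    "hes6": "k_d,HES6",
}


def hill_factor(regulator_conc: float, H: float, h: int, n: int = 1) -> float:
    """Generalised repressive Hill factor ``H^(n*h) / (H^(n*h) + x^(n*h))``.

    Strictly decreasing in the regulator concentration, equal to 1 at
    zero regulator and to 0.5 at ``x = H``.  ``h`` is the number of
    binding sites; ``n`` = 2 when the repressor binds as a dimer.
    """
    if H <= 0:
        raise ValueError("Hill constant H must be positive")
    if h < 1:
        raise ValueError("Hill coefficient h must be >= 1")
    if n not in (1, 2):
        raise ValueError("stoichiometry n must be 1 or 2")
    if regulator_conc < 0:
        raise ValueError("regulator concentration must be non-negative")
    e = n * h
    He = H**e
    return He / (He + regulator_conc**e)


def transcription_rate(
    gene: str,
    state: np.ndarray,
    params: ParameterSet,
    delp: float = 0.0,
    wiring: Wiring | None = None,
) -> float:
    """Transcription rate ``k_i`` of ``gene`` at the given network state.

    ``k_i = k_i,0 * prod(repressive Hill factors) * (1 + sites*[NRB])
    * ebox(Mash1-E47)`` — the NRB term only while a delta signal is
    present, the E-box term only for the proneural genes.
    """
    wiring = wiring or default_wiring()
    reg = wiring.regulation(gene)  # raises KeyError for unknown gene
    state = np.asarray(state, dtype=float)
    k = params[reg.k0]
    for term in reg.repressors:
        k *= hill_factor(state[sp.SPECIES_INDEX[term.regulator]], params[term.H], term.h, term.n)
    # NRB activation persists while the complex exists (delta gates NICD
    # generation upstream, not the complex's activity)
    if reg.rbp_site_count:
        k *= 1.0 + reg.rbp_site_count * state[sp.NRB]
    if reg.ebox is not None:
        d = state[sp.DIMER_MASH1_E47]
        act = d**reg.ebox.g / (params[reg.ebox.H] ** reg.ebox.g + d**reg.ebox.g)
        k *= (1.0 + act) if wiring.ebox_mode_for(gene) == "basal" else act
    return k


def dimer_fluxes(
    state: np.ndarray, params: ParameterSet, wiring: Wiring | None = None
) -> dict[str, float]:
    """Heterodimer formation/dissociation fluxes (concentration/min).

    Mash1-E47 formation is attenuated by the Hes1 dominant-negative
    factor and its dissociation does *not* return Mash1 (the protein is
    phosphorylated in the dimer).  The Hes1-Hes6 monomer pools and
    return-on-dissociation convention follow the wiring.
    """
    wiring = wiring or default_wiring()
    state = np.asarray(state, dtype=float)
    hes1_n = state[sp.prot_nuc("hes1")]
    attn = params["k_dom,neg"] / (params["k_dom,neg"] + hes1_n)
    pool = sp.prot_nuc if wiring.h16_compartment == "nuclear" else sp.prot_cyt
    return {
        "hes1_hes6_formation": params["k_0,HES1,6"]
        * state[pool("hes1")]
        * state[pool("hes6")],
        "hes1_hes6_dissociation": params["k_d,HES1,6"] * state[sp.DIMER_HES1_HES6],
        "mash1_e47_formation": params["k_0,[M-E47]"]
        * state[sp.prot_nuc("mash1")]
        * params["E47_total"]
        * attn,
        "mash1_e47_dissociation": params["k_d,[M-E47]"] * state[sp.DIMER_MASH1_E47],
    }


def nicd_fluxes(
    state: np.ndarray, params: ParameterSet, delp: float = 0.0
) -> dict[str, float]:
    """NICD branch fluxes: delta-gated cleavage from cytoplasmic Notch,
    saturating nuclear import, NRB complex formation/dissociation (RBPJ
    is returned on dissociation, NICD is degraded), and degradation."""
    state = np.asarray(state, dtype=float)
    notch_c = state[sp.prot_cyt("notch1")]
    nicd_c, nicd_n = state[sp.NICD_CYT], state[sp.NICD_NUC]
    return {
        "generation": delp * params["k_NICD"] * notch_c / (params["K_RBP-J"] + notch_c),
        "nuclear_import": params["k_NICD,import"] * nicd_c / (params["K_NICD"] + nicd_c),
        "nrb_formation": params["k_0,Nicd-RBP"] * nicd_n * state[sp.prot_nuc("rbpj")],
        "nrb_dissociation": params["k_d,NRB"] * state[sp.NRB],
        "nicd_cyt_degradation": params["k_d,NICD"] * nicd_c,
        "nicd_nuc_degradation": params["k_d,NICD"] * nicd_n,
    }


def ode_rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet,
    protocol: Protocol | None = None,
    wiring: Wiring | None = None,
) -> np.ndarray:
    """Time derivative of the 25-component state (reference implementation).

    Raises ``ValueError`` naming the offending component if the state
    contains NaN/Inf.
    """
    state = np.asarray(state, dtype=float)
    bad = ~np.isfinite(state)
    if bad.any():
        name = sp.SPECIES[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"non-finite state component {name!r} at t={t}")
    protocol = protocol or Protocol()
    wiring = wiring or default_wiring()
    delp, sources, ramped = protocol.resolve(t, params)
    if ramped:
        params = params.replace_named(ramped)

    a, b = params["a_mRNA"], params["b_prot"]
    dy = np.zeros(sp.N_SPECIES)
    for gene in sp.GENES:
        i = sp.mrna_nuc(gene)
        kd_m = params[_KD_MRNA_KEY[gene]]
        kd_p = params[_KD_PROT_KEY[gene]]
        c = params[_C_KEY[gene]]
        k = transcription_rate(gene, state, params, delp, wiring)
        dy[i] = k - (kd_m + a) * state[i]
        dy[i + 1] = a * state[i] - kd_m * state[i + 1]
        dy[i + 2] = c * state[i + 1] - (kd_p + b) * state[i + 2]
        dy[i + 3] = b * state[i + 2] - kd_p * state[i + 3]

    dm = dimer_fluxes(state, params, wiring)
    nf = nicd_fluxes(state, params, delp)
    if wiring.h16_returns_monomers:
        h16 = dm["hes1_hes6_formation"] - dm["hes1_hes6_dissociation"]
    else:
        h16 = dm["hes1_hes6_formation"]
    pool = sp.prot_nuc if wiring.h16_compartment == "nuclear" else sp.prot_cyt
    dy[pool("hes1")] -= h16
    dy[pool("hes6")] -= h16
    dy[sp.prot_nuc("mash1")] -= dm["mash1_e47_formation"]
    dy[sp.prot_nuc("rbpj")] -= nf["nrb_formation"] - nf["nrb_dissociation"]
    dy[sp.DIMER_HES1_HES6] = h16
    dy[sp.DIMER_MASH1_E47] = dm["mash1_e47_formation"] - dm["mash1_e47_dissociation"]
    dy[sp.NICD_CYT] = nf["generation"] - nf["nuclear_import"] - nf["nicd_cyt_degradation"]
    dy[sp.NICD_NUC] = nf["nuclear_import"] - nf["nrb_formation"] - nf["nicd_nuc_degradation"]
    dy[sp.NRB] = nf["nrb_formation"] - nf["nrb_dissociation"]

    for idx, rate in sources:
        dy[idx] += rate
    return dy


@dataclass
class DeltaNotchModel:
    """Single-cell Delta1/Notch1 network with a fixed parameterisation.

    Parameters
    ----------
    params
        Model constants; defaults to the calibrated optimum.
    wiring
        Regulatory map; defaults to the packaged wiring.
    options
        Solver settings (stiff-capable LSODA, rtol 1e-8 / atol 1e-10,
        1-min output grid).
    """

    params: ParameterSet = None  # type: ignore[assignment]
    wiring: Wiring = None  # type: ignore[assignment]
    options: SolverOptions = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = table2_parameters()
        if self.wiring is None:
            self.wiring = default_wiring()
        if self.options is None:
            self.options = SolverOptions()

    @classmethod
    def from_files(
        cls, params_path, wiring_path=None, options: SolverOptions | None = None
    ) -> "DeltaNotchModel":
        return cls(
            params=ParameterSet.load(params_path),
            wiring=Wiring.load(wiring_path) if wiring_path else None,
            options=options,
        )

    def with_params(self, params: ParameterSet) -> "DeltaNotchModel":
        return DeltaNotchModel(params, self.wiring, self.options)

    def rhs(self, t: float, state: np.ndarray, protocol: Protocol | None = None):
        return ode_rhs(t, state, self.params, protocol, self.wiring)

    def simulate(
        self,
        t_end: float = 3000.0,
        protocol: Protocol | None = None,
        initial: np.ndarray | None = None,
        output_window: tuple[float, float] | None = None,
    ) -> Trajectory:
        return integrate(
            self.params,
            t_end,
            protocol=protocol,
            initial=initial,
            wiring=self.wiring,
            options=self.options,
            output_window=output_window,
        )

    def parameter_space(self, span: float = 0.9) -> ParameterSpace:
        return ParameterSpace(center=self.params, span=span)

    def fit(self, m: int = 10, skip: int = 1, span: float = 0.9, **kwargs):
        """Qualitative-cost calibration: Sobol scan of the +/-span
        hypercube around the current parameters (see
        :func:`notchfate.calibration.calibrate`)."""
        from .calibration import calibrate

        return calibrate(self.parameter_space(span), m=m, skip=skip, wiring=self.wiring, **kwargs)

    def sensitivity(self, n_samples: int = 512, span: float = 0.9, **kwargs):
        """Derivative-based global sensitivity analysis around the current
        parameters (see :func:`notchfate.sensitivity.dgsm`)."""
        from .sensitivity import dgsm

        return dgsm(self.parameter_space(span), n_samples=n_samples, wiring=self.wiring, **kwargs)
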