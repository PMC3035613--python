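"""Compiled right-hand side of the 25-component ODE system.

This is the hot path: the calibration scan and the derivative-based
sensitivity analysis both run tens of thousands of integrations, so the
RHS is JIT-compiled with numba.  ``model.ode_rhs`` provides an equivalent
pure-Python implementation used as the readable reference; a unit test
asserts the two agree.

Parameter-vector indices are frozen at import time from the canonical
parameter ordering; wiring arrays come pre-compiled from
:class:`notchfate.wiring.Wiring`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import PARAM_INDEX
from .species import DIMER_HES1_HES6, DIMER_MASH1_E47, NICD_CYT, NICD_NUC, NRB

# frozen parameter-vector positions (compile-time constants for numba)
_I_KD_ME47 = PARAM_INDEX["k_d,[M-E47]"]
_I_KD_HES16 = PARAM_INDEX["k_d,HES1,6"]
_I_KD_NRB = PARAM_INDEX["k_d,NRB"]
_I_KDOM = PARAM_INDEX["k_dom,neg"]
_I_K0_ME47 = PARAM_INDEX["k_0,[M-E47]"]
_I_K0_HES16 = PARAM_INDEX["k_0,HES1,6"]
_I_C0 = PARAM_INDEX["c_HES1"]  # translation rates, contiguous in gene order
_I_A = PARAM_INDEX["a_mRNA"]
_I_B = PARAM_INDEX["b_prot"]
_I_KD_NICD = PARAM_INDEX["k_d,NICD"]
_I_K0_NICDRBP = PARAM_INDEX["k_0,Nicd-RBP"]
_I_K_NICD = PARAM_INDEX["K_NICD"]
_I_K_RBPJ = PARAM_INDEX["K_RBP-J"]
_I_KNICD_GEN = PARAM_INDEX["k_NICD"]
_I_E47 = PARAM_INDEX["E47_total"]
_I_KNICD_IMP = PARAM_INDEX["k_NICD,import"]

# species offsets
_HES1_PN = 3
_RBPJ_PN = 7
_NOTCH_PC = 10
_MASH1_PN = 15
_HES6_PN = 19


@njit(cache=True, fastmath=False)
def rhs_core(
    t,
    y,
    P,
    rep_gene,
    rep_reg,
    rep_H,
    rep_nh,
    k0_idx,
    nrb_sites,
    ebox_H,
    ebox_g,
    domneg,
    ebox_basal,
    h16_return,
    h16_nuclear,
    delp,
    pulse_idx,
    pulse_rate,
    ramp_idx,
    ramp_v0,
    ramp_v1,
    ramp_t0,
    ramp_t1,
):  # pragma: no cover - exercised via model/simulation tests
    # effective parameters under active linear ramps
    Pe = P.copy()
    for r in range(ramp_idx.shape[0]):
        t0 = ramp_t0[r]
        t1 = ramp_t1[r]
        if t <= t0:
            v = ramp_v0[r]
        elif t >= t1:
            v = ramp_v1[r]
        else:
            v = ramp_v0[r] + (ramp_v1[r] - ramp_v0[r]) * (t - t0) / (t1 - t0)
        Pe[ramp_idx[r]] = v

    dme = y[DIMER_MASH1_E47]
    hes1_n = y[_HES1_PN]
    nrb = y[NRB]
    # monomer pools feeding Hes1-Hes6 dimerisation
    if h16_nuclear:
        h16_i1, h16_i6 = _HES1_PN, _HES6_PN
    else:
        h16_i1, h16_i6 = _HES1_PN - 1, _HES6_PN - 1

    # transcription rate per gene
    k_tx = np.empty(5)
    for g in range(5):
        k = Pe[k0_idx[g]]
        # the NICD-RBPJ complex activates for as long as it exists; the
        # delta signal gates NICD generation, not NRB activity
        if nrb_sites[g] > 0.0:
            k *= 1.0 + nrb_sites[g] * nrb
        if ebox_H[g] >= 0:
            Hg = Pe[ebox_H[g]]
            num = dme ** ebox_g[g]
            act = num / (Hg ** ebox_g[g] + num)
            k *= (1.0 + act) if ebox_basal[g] else act
        k_tx[g] = k
    for j in range(rep_gene.shape[0]):
        x = y[rep_reg[j]]
        H = Pe[rep_H[j]]
        e = rep_nh[j]
        Hp = H**e
        k_tx[rep_gene[j]] *= Hp / (Hp + x**e)

    a = Pe[_I_A]
    b = Pe[_I_B]

    # dimer fluxes (Hes1 dominant-negative attenuation of Mash1-E47 formation)
    attn = Pe[_I_KDOM] / (Pe[_I_KDOM] + hes1_n) if domneg[3] else 1.0
    f_h16 = Pe[_I_K0_HES16] * y[h16_i1] * y[h16_i6]
    d_h16 = Pe[_I_KD_HES16] * y[DIMER_HES1_HES6]
    f_me = Pe[_I_K0_ME47] * y[_MASH1_PN] * Pe[_I_E47] * attn
    d_me = Pe[_I_KD_ME47] * dme

    # NICD fluxes
    notch_c = y[_NOTCH_PC]
    gen = delp * Pe[_I_KNICD_GEN] * notch_c / (Pe[_I_K_RBPJ] + notch_c)
    imp = Pe[_I_KNICD_IMP] * y[NICD_CYT] / (Pe[_I_K_NICD] + y[NICD_CYT])
    f_nrb = Pe[_I_K0_NICDRBP] * y[NICD_NUC] * y[_RBPJ_PN]
    d_nrb = Pe[_I_KD_NRB] * nrb

    dy = np.zeros(25)
    for g in range(5):
        i = 4 * g
        kd_m = Pe[g]
        kd_p = Pe[5 + g]
        c = Pe[_I_C0 + g]
        dy[i] = k_tx[g] - (kd_m + a) * y[i]
        dy[i + 1] = a * y[i] - kd_m * y[i + 1]
        dy[i + 2] = c * y[i + 1] - (kd_p + b) * y[i + 2]
        dy[i + 3] = b * y[i + 2] - kd_p * y[i + 3]

    # net dimer consumption from the monomer pools
    if h16_return:
        dy[h16_i1] += -f_h16 + d_h16
        dy[h16_i6] += -f_h16 + d_h16
    else:
        dy[h16_i1] += -f_h16
        dy[h16_i6] += -f_h16
    dy[_MASH1_PN] += -f_me  # Mash1 is phosphorylated in the dimer: not returned
    dy[_RBPJ_PN] += -f_nrb + d_nrb

    dy[DIMER_HES1_HES6] = f_h16 - d_h16
    dy[DIMER_MASH1_E47] = f_me - d_me
    dy[NICD_CYT] = gen - imp - Pe[_I_KD_NICD] * y[NICD_CYT]
    dy[NICD_NUC] = imp - f_nrb - Pe[_I_KD_NICD] * y[NICD_NUC]
    dy[NRB] = f_nrb - d_nrb

    # constant-source pulses on cytoplasmic protein pools
    for q in range(pulse_idx.shape[0]):
        dy[pulse_idx[q]] += pulse_rate[q]

    return dy


_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


def make_rhs(params_vec, wiring_arrays, delp=0.0, pulses=None, ramps=None):
    """Bind a parameter vector, wiring and (constant-within-segment)
    protocol state into a ``f(t, y) -> dy`` callable for the integrator.

    ``pulses`` is a list of ``(species_index, rate)``; ``ramps`` a list of
    ``(param_index, v0, v1, t0, t1)`` linear ramps (evaluated inside the
    kernel because they vary continuously in time).
    """
    w = wiring_arrays
    if pulses:
        p_idx = np.array([p[0] for p in pulses], dtype=np.int64)
        p_rate = np.array([p[1] for p in pulses], dtype=np.float64)
    else:
        p_idx, p_rate = _EMPTY_I, _EMPTY_F
    if ramps:
        r_idx = np.array([r[0] for r in ramps], dtype=np.int64)
        r_v0 = np.array([r[1] for r in ramps], dtype=np.float64)
        r_v1 = np.array([r[2] for r in ramps], dtype=np.float64)
        r_t0 = np.array([r[3] for r in ramps], dtype=np.float64)
        r_t1 = np.array([r[4] for r in ramps], dtype=np.float64)
    else:
        r_idx, r_v0, r_v1, r_t0, r_t1 = _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F
    P = np.ascontiguousarray(params_vec, dtype=np.float64)
    delp = float(delp)

    def f(t, y):
        return rhs_core(
            t,
            y,
            P,
            w["rep_gene"],
            w["rep_reg"],
            w["rep_H"],
            w["rep_nh"],
            w["k0_idx"],
            w["nrb_sites"],
            w["ebox_H"],
            w["ebox_g"],
            w["domneg"],
            w["ebox_basal"],
            w["h16_return"],
            w["h16_nuclear"],
            delp,
            p_idx,
            p_rate,
            r_idx,
            r_v0,
            r_v1,
            r_t0,
            r_t1,
        )

    return f
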