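"""Unit tests of the regulatory-network building blocks: Hill factors,
transcription rates, dimer/NICD fluxes and the assembled right-hand side
(including agreement between the reference and compiled implementations)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notchfate import (
    Protocol,
    default_wiring,
    dimer_fluxes,
    hill_factor,
    nicd_fluxes,
    ode_rhs,
    table2_parameters,
    transcription_rate,
)
from notchfate._rhs import make_rhs
from notchfate.species import (
    DIMER_MASH1_E47,
    N_SPECIES,
    NICD_CYT,
    NICD_NUC,
    NRB,
    SPECIES_INDEX,
    mrna_nuc,
    prot_nuc,
)


class TestHillFactor:
    def test_zero_repressor_gives_no_repression(self):
        assert hill_factor(0.0, H=10.0, h=3, n=2) == 1.0

    def test_half_saturation_at_hill_constant(self):
        for h, n in [(1, 1), (3, 2), (2, 1)]:
            assert hill_factor(3.7486, H=3.7486, h=h, n=n) == pytest.approx(0.5)

    def test_matches_independent_closed_form(self):
        # independent high-precision evaluation in log space
        x, H, h, n = 5.0, 3.7486, 3, 2
        e = n * h
        expected = 1.0 / (1.0 + math.exp(e * (math.log(x) - math.log(H))))
        assert hill_factor(x, H, h, n) == pytest.approx(expected, rel=1e-12)

    def test_classic_single_site_form_recovered(self):
        # n=1 reduces to the classic K^h/(K^h + p^h)
        p, K, h = 7.0, 10.0, 4
        assert hill_factor(p, K, h, 1) == pytest.approx(K**h / (K**h + p**h))

    @given(
        x1=st.floats(0.0, 100.0),
        x2=st.floats(0.0, 100.0),
        H=st.floats(0.1, 50.0),
        h=st.integers(1, 4),
        n=st.sampled_from([1, 2]),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_and_bounded(self, x1, x2, H, h, n):
        lo, hi = sorted([x1, x2])
        f_lo, f_hi = hill_factor(lo, H, h, n), hill_factor(hi, H, h, n)
        assert 0.0 < f_hi <= f_lo <= 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hill_factor(1.0, H=0.0, h=3, n=2)
        with pytest.raises(ValueError):
            hill_factor(1.0, H=1.0, h=0, n=2)
        with pytest.raises(ValueError):
            hill_factor(1.0, H=1.0, h=1, n=3)


class TestTranscriptionRate:
    def setup_method(self):
        self.params = table2_parameters()
        self.wiring = default_wiring()

    def test_zero_state_yields_maximal_rate(self):
        state = np.zeros(N_SPECIES)
        k = transcription_rate("hes1", state, self.params, delp=0)
        assert k == pytest.approx(self.params["k_0,HES1"]) == pytest.approx(1.0056)

    def test_nrb_activation_is_linear_in_complex(self):
        # hes1 carries 2 RBPJ sites: rate = k0 * (1 + 2 q) at NRB = q
        state = np.zeros(N_SPECIES)
        state[NRB] = 1.0
        k = transcription_rate("hes1", state, self.params, delp=1)
        assert k == pytest.approx(self.params["k_0,HES1"] * 3.0)

    def test_saturating_repressor_shuts_down_mash1(self):
        state = np.zeros(N_SPECIES)
        state[prot_nuc("hes1")] = 1e6
        assert transcription_rate("mash1", state, self.params) < 1e-9

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            transcription_rate("dll1", np.zeros(N_SPECIES), self.params)

    def test_monotone_repression_in_each_repressor(self):
        state = np.full(N_SPECIES, 1.0)
        for gene in ("hes1", "rbpj", "notch1", "mash1"):
            for reg in default_wiring().regulation(gene).repressors:
                idx = SPECIES_INDEX[reg.regulator]
                rates = []
                for conc in (0.0, 1.0, 5.0, 50.0):
                    s = state.copy()
                    s[idx] = conc
                    rates.append(transcription_rate(gene, s, self.params))
                assert all(a >= b for a, b in zip(rates, rates[1:])), (gene, reg)


class TestDimerFluxes:
    def test_all_zero_state_has_zero_fluxes(self):
        fluxes = dimer_fluxes(np.zeros(N_SPECIES), table2_parameters())
        assert all(v == 0.0 for v in fluxes.values())

    def test_dominant_negative_half_attenuation(self):
        # at Hes1 = k_dom,neg the Mash1-E47 formation halves
        params = table2_parameters()
        state = np.zeros(N_SPECIES)
        state[prot_nuc("mash1")] = 2.0
        free = dimer_fluxes(state, params)["mash1_e47_formation"]
        state[prot_nuc("hes1")] = params["k_dom,neg"]
        attenuated = dimer_fluxes(state, params)["mash1_e47_formation"]
        assert attenuated == pytest.approx(free / 2.0)

    def test_isolated_dimer_pool_equilibrates_at_flux_ratio(self):
        # dD/dt = f - k D has the closed-form fixed point D* = f/k
        from scipy.integrate import solve_ivp

        f, k = 0.05, 0.0289
        sol = solve_ivp(lambda t, y: [f - k * y[0]], (0, 2000), [0.0], rtol=1e-10)
        assert sol.y[0, -1] == pytest.approx(f / k, rel=1e-4)


class TestNicdFluxes:
    def test_autonomous_reduction_without_delta(self):
        """With delp = 0 and empty NICD/NRB pools the whole NICD branch is
        silent and the autonomous oscillator is recovered."""
        state = np.full(N_SPECIES, 2.0)
        state[NICD_CYT] = state[NICD_NUC] = state[NRB] = 0.0
        fluxes = nicd_fluxes(state, table2_parameters(), delp=0)
        assert all(v == 0.0 for v in fluxes.values())
        dy = ode_rhs(0.0, state, table2_parameters())
        assert dy[NICD_CYT] == dy[NICD_NUC] == dy[NRB] == 0.0

    def test_nrb_decays_exponentially_when_formation_is_off(self):
        params = table2_parameters()
        state = np.zeros(N_SPECIES)
        state[NRB] = 0.7
        fluxes = nicd_fluxes(state, params, delp=0)
        assert fluxes["nrb_dissociation"] == pytest.approx(0.0028 * 0.7)
        # over Delta t the isolated pool follows exp(-k t)
        dt = 500.0
        assert 0.7 * math.exp(-0.0028 * dt) == pytest.approx(
            0.7 * math.e ** (-params["k_d,NRB"] * dt)
        )


class TestOdeRhs:
    def setup_method(self):
        self.params = table2_parameters()

    def test_zero_state_sources_are_transcription_only(self):
        # hes6 is gated behind the E-box activator, so at an all-zero state
        # its transcription is silent; the other four genes source their
        # nuclear mRNA at the maximal rate
        dy = ode_rhs(0.0, np.zeros(N_SPECIES), self.params)
        nonzero = set(int(i) for i in np.flatnonzero(dy))
        assert nonzero == {mrna_nuc(g) for g in ("hes1", "rbpj", "notch1", "mash1")}

    def test_pure_decay_matches_closed_form(self):
        # a lone species with only degradation active decays as exp(-k t)
        from notchfate.parameters import ParameterSet

        zeroed = {k: 0.0 for k in table2_parameters().to_dict()}
        zeroed.update(
            {
                k: 1.0
                for k in (
                    "H_HES1",
                    "H_RBP-J",
                    "K_HES1",
                    "H_MASH1",
                    "H_HES6",
                    "k_dom,neg",
                    "K_NICD",
                    "K_RBP-J",
                )
            }
        )
        zeroed["k_d,NICD"] = 0.01
        params = ParameterSet(zeroed)
        state = np.zeros(N_SPECIES)
        state[NICD_CYT] = 1.0
        dy = ode_rhs(0.0, state, params)
        assert dy[NICD_CYT] == pytest.approx(-0.01)

    def test_nan_state_names_offending_component(self):
        state = np.zeros(N_SPECIES)
        state[DIMER_MASH1_E47] = np.nan
        with pytest.raises(ValueError, match="dimer_mash1_e47"):
            ode_rhs(0.0, state, self.params)

    def test_reference_and_compiled_rhs_agree(self, rng):
        """The readable Python RHS and the numba kernel are the same
        function, on random non-negative states, with and without delta."""
        wiring = default_wiring()
        f0 = make_rhs(self.params.to_vector(), wiring.arrays, delp=0.0)
        f1 = make_rhs(self.params.to_vector(), wiring.arrays, delp=1.0)
        for _ in range(25):
            y = rng.uniform(0.0, 20.0, N_SPECIES)
            np.testing.assert_allclose(
                f0(0.0, y), ode_rhs(0.0, y, self.params), rtol=1e-12, atol=1e-14
            )
            proto = Protocol(delta_window=(0.0, 100.0))
            np.testing.assert_allclose(
                f1(0.0, y), ode_rhs(50.0, y, self.params, proto), rtol=1e-12, atol=1e-14
            )

    def test_dimer_conservation_under_pure_binding(self):
        """With synthesis and degradation off, Hes1 + Hes1-in-dimer is
        conserved by Hes1-Hes6 binding/unbinding."""
        from notchfate.parameters import ParameterSet
        from notchfate.wiring import Wiring

        zeroed = {k: 0.0 for k in table2_parameters().to_dict()}
        zeroed.update(
            {
                k: 1.0
                for k in (
                    "H_HES1",
                    "H_RBP-J",
                    "K_HES1",
                    "H_MASH1",
                    "H_HES6",
                    "k_dom,neg",
                    "K_NICD",
                    "K_RBP-J",
                )
            }
        )
        zeroed["k_0,HES1,6"] = 0.01
        zeroed["k_d,HES1,6"] = 0.02
        params = ParameterSet(zeroed)
        doc = default_wiring().to_dict()
        doc["h16_compartment"] = "nuclear"  # put binding and pool in one place
        wiring = Wiring.from_dict(doc)
        state = np.zeros(N_SPECIES)
        state[prot_nuc("hes1")] = 3.0
        state[prot_nuc("hes6")] = 4.0
        state[SPECIES_INDEX["dimer_hes1_hes6"]] = 1.0
        dy = ode_rhs(0.0, state, params, wiring=wiring)
        total_hes1_rate = dy[prot_nuc("hes1")] + dy[SPECIES_INDEX["dimer_hes1_hes6"]]
        assert total_hes1_rate == pytest.approx(0.0, abs=1e-14)
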