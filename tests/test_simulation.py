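import numpy as np
import pytest

from notchfate import (
    Protocol,
    Pulse,
    Ramp,
    SolverOptions,
    Trajectory,
    integrate,
    table2_parameters,
)
from notchfate.parameters import ParameterSet
from notchfate.species import N_SPECIES, NICD_CYT, SPECIES


def _silent_params(**overrides):
    base = {k: 0.0 for k in table2_parameters().to_dict()}
    base.update(
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
    base.update(overrides)
    return ParameterSet(base)


def test_zero_transcription_zero_state_stays_zero():
    traj = integrate(_silent_params(), 500.0, initial=np.zeros(N_SPECIES))
    assert np.all(traj.states == 0.0)


def test_single_species_decay_matches_closed_form():
    params = _silent_params(**{"k_d,NICD": 0.02})
    y0 = np.zeros(N_SPECIES)
    y0[NICD_CYT] = 1.0
    traj = integrate(params, 300.0, initial=y0)
    expected = np.exp(-0.02 * traj.times)
    np.testing.assert_allclose(traj.column("nicd_cyt"), expected, rtol=1e-6, atol=1e-9)


def test_uniform_grid_and_shape(baseline_t2):
    assert baseline_t2.states.shape == (len(baseline_t2), 25)
    np.testing.assert_allclose(np.diff(baseline_t2.times), 1.0)
    assert np.all(np.isfinite(baseline_t2.states))
    assert np.all(baseline_t2.states >= 0.0)


def test_segmented_equals_single_shot_for_inert_protocol(model_t2):
    """A protocol whose windows carry no effect (zero-magnitude pulse)
    forces segmentation but must not change the solution."""
    plain = model_t2.simulate(600.0)
    proto = Protocol(pulses=(Pulse("hes1", 0.0, (200.0, 400.0), rate=1.0),))
    segmented = model_t2.simulate(600.0, protocol=proto)
    assert segmented.diagnostics["segments"] == 3
    np.testing.assert_allclose(segmented.states, plain.states, rtol=1e-6, atol=1e-8)


def test_grid_refinement_stability(model_t2, baseline_t2):
    """Halving solver tolerances changes the final-window Hes1 mean by
    far less than 0.1%."""
    from notchfate import DeltaNotchModel

    tighter = DeltaNotchModel(
        params=model_t2.params,
        wiring=model_t2.wiring,
        options=SolverOptions(rtol=5e-9, atol=5e-11),
    )
    a = baseline_t2.window(2000, 3000).column("hes1_prot_nuc").mean()
    b = tighter.simulate(3000.0).window(2000, 3000).column("hes1_prot_nuc").mean()
    assert abs(a - b) / a < 1e-3


def test_protocol_resolution():
    params = table2_parameters()
    ramp = Ramp("k_d,HRN", 1.0, 10.0, (100.0, 200.0))
    pulse = Pulse("hes1", 5.0, (50.0, 150.0), rate=0.2)
    proto = Protocol(delta_window=(80.0, 120.0), pulses=(pulse,), ramps=(ramp,))
    # before all windows
    delp, sources, ramped = proto.resolve(10.0, params)
    assert (delp, sources) == (0.0, []) and ramped["k_d,HRN"] == 1.0
    # ramp midpoint interpolates linearly: v -> 10v at t=150 gives 5.5v
    _, _, ramped = proto.resolve(150.0, params)
    assert ramped["k_d,HRN"] == pytest.approx(5.5)
    # after the ramp the end value holds
    _, _, ramped = proto.resolve(1000.0, params)
    assert ramped["k_d,HRN"] == 10.0
    # pulse adds magnitude x reference rate while active
    delp, sources, _ = proto.resolve(100.0, params)
    assert delp == 1.0
    assert sources == [(Pulse("hes1", 1, (0, 1), 1).species_index, pytest.approx(1.0))]


def test_protocol_validation():
    with pytest.raises(ValueError):
        Ramp("not_a_parameter", 1.0, 2.0, (0.0, 1.0))
    with pytest.raises(ValueError):
        Pulse("hes1", 1.0, (10.0, 5.0))
    with pytest.raises(ValueError):
        Protocol(ramps=(Ramp("k_d,HRN", 1, 2, (0, 1)), Ramp("k_d,HRN", 2, 3, (1, 2))))


def test_pulse_adds_constant_source(model_t2):
    """During the pulse window the target's cytoplasmic protein gains a
    constant source: magnitude x reference rate."""
    proto = Protocol(pulses=(Pulse("hes1", 5.0, (0.0, 100.0), rate=0.1),))
    with_pulse = model_t2.simulate(100.0, protocol=proto)
    without = model_t2.simulate(100.0)
    gain = with_pulse.column("hes1_prot_cyt") - without.column("hes1_prot_cyt")
    # before feedback through the nucleus kicks in, the excess follows the
    # closed form (rate/k)(1 - exp(-k t)) with k the pool's total loss rate
    k = table2_parameters()["k_d,HES1"] + table2_parameters()["b_prot"]
    t = 10
    expected = (0.5 / k) * (1.0 - np.exp(-k * with_pulse.times[t]))
    assert gain[t] == pytest.approx(expected, rel=0.02)


def test_trajectory_round_trip(tmp_path, model_t2):
    proto = Protocol(delta_window=(100.0, 200.0))
    traj = model_t2.simulate(300.0, protocol=proto)
    path = tmp_path / "traj.csv"
    traj.save(path)
    loaded = Trajectory.load(path)
    assert list(loaded.protocol.delta_window) == [100.0, 200.0]
    np.testing.assert_allclose(loaded.states, traj.states, rtol=1e-12)
    assert loaded.protocol.to_dict() == traj.protocol.to_dict()
    header = path.read_text().splitlines()[0]
    assert header.split(",") == ["time_min", *SPECIES]


def test_output_window_restricts_grid(model_t2):
    traj = model_t2.simulate(500.0, output_window=(400.0, 500.0))
    assert traj.times[0] == 400.0 and traj.times[-1] == 500.0
    full = model_t2.simulate(500.0)
    np.testing.assert_allclose(
        traj.states, full.window(400, 500).states, rtol=1e-6, atol=1e-9
    )


def test_invalid_inputs_rejected(model_t2):
    with pytest.raises(ValueError):
        model_t2.simulate(-5.0)
    with pytest.raises(ValueError):
        model_t2.simulate(100.0, initial=np.full(N_SPECIES, -1.0))
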