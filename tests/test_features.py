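import math

import numpy as np
import pytest

from notchfate import (
    FateLabel,
    antiphase_check,
    classify_fate,
    detect_peaks,
    oscillation_features,
    phase_plane,
    return_to_rest_lag,
)
from notchfate.synthetic import TraceSpec, generate_paired_network_mimic, generate_trace
from notchfate.simulation import Trajectory
from notchfate.protocols import Protocol
from notchfate.species import N_SPECIES, SPECIES_INDEX


def _trajectory_from_trace(spec: TraceSpec, species="hes1_prot_nuc") -> Trajectory:
    t, y = generate_trace(spec)
    states = np.zeros((t.size, N_SPECIES))
    states[:, SPECIES_INDEX[species]] = y
    return Trajectory(t, states, Protocol(), {})


class TestDetectPeaks:
    def test_pure_sinusoid_recovers_all_peaks(self):
        t, y = generate_trace(TraceSpec(period=120.0, duration=1000.0))
        peaks = detect_peaks(t, y)
        assert len(peaks) == 8
        np.testing.assert_allclose(np.diff(peaks), 120.0, atol=1.0)

    def test_constant_series_has_no_peaks(self):
        t = np.arange(100.0)
        assert detect_peaks(t, np.full(100, 3.0)).size == 0

    def test_noisy_trace_recovers_injected_peak_count(self):
        spec = TraceSpec(period=120.0, duration=1200.0, amplitude=2.0, noise_sd=0.1, seed=7)
        t, y = generate_trace(spec)
        # interior cosine maxima at 120, 240, ..., 1080 (endpoints excluded)
        injected = math.floor(1200.0 / 120.0) - 1
        assert abs(len(detect_peaks(t, y)) - injected) <= 1

    def test_short_or_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            detect_peaks(np.arange(5.0), np.arange(5.0))


class TestOscillationFeatures:
    @pytest.mark.parametrize("period", [60.0, 120.0, 180.0, 300.0])
    def test_period_exact_to_grid_resolution_on_sinusoids(self, period):
        traj = _trajectory_from_trace(TraceSpec(period=period, duration=4 * 300.0))
        f = oscillation_features(traj, "hes1_prot_nuc")
        assert f.period == pytest.approx(period, abs=traj.step)
        assert f.period_cv < 0.02
        # amplitude is peak-to-trough: 2 x the cosine amplitude
        assert f.relative_amplitude == pytest.approx(2 * 2.0 / 5.0, rel=0.05)

    def test_damped_trace_amplitude_declines_between_subwindows(self):
        traj = _trajectory_from_trace(TraceSpec(damping=5e-4, duration=2000.0))
        first = oscillation_features(traj, "hes1_prot_nuc", (0.0, 1000.0))
        second = oscillation_features(traj, "hes1_prot_nuc", (1000.0, 2000.0))
        assert second.relative_amplitude < first.relative_amplitude
        # envelope ratio over 1000 min is exp(-0.5) ~ 0.61
        assert second.relative_amplitude / first.relative_amplitude == pytest.approx(
            math.exp(-5e-4 * 1000.0), rel=0.2
        )

    def test_too_few_peaks_flagged(self):
        traj = _trajectory_from_trace(TraceSpec(period=900.0, duration=1000.0))
        f = oscillation_features(traj, "hes1_prot_nuc")
        assert f.flagged and not f.period_defined

    def test_rescaling_invariance(self):
        """Uniform concentration rescaling leaves period, CV and relative
        amplitude unchanged."""
        spec = TraceSpec(period=120.0, duration=1500.0, noise_sd=0.05, seed=3)
        traj = _trajectory_from_trace(spec)
        scaled = Trajectory(traj.times, traj.states * 37.0, Protocol(), {})
        f1 = oscillation_features(traj, "hes1_prot_nuc")
        f2 = oscillation_features(scaled, "hes1_prot_nuc")
        assert f1.period == pytest.approx(f2.period)
        assert f1.relative_amplitude == pytest.approx(f2.relative_amplitude, rel=1e-9)


class TestAntiphase:
    def test_half_period_offset_interleaves(self):
        traj = generate_paired_network_mimic(TraceSpec(duration=1500.0))
        ok, offsets = antiphase_check(traj)
        assert ok is True
        assert np.allclose(offsets, 0.5, atol=0.05)

    def test_in_phase_signals_fail(self):
        spec = TraceSpec(duration=1500.0)
        traj = generate_paired_network_mimic(
            spec, spec_mash1=TraceSpec(duration=1500.0, mean=2.5, amplitude=1.0)
        )
        ok, _ = antiphase_check(traj)
        assert ok is False

    def test_missing_peaks_indeterminate(self):
        traj = generate_paired_network_mimic(TraceSpec(duration=1500.0))
        traj.states[:, SPECIES_INDEX["mash1_prot_nuc"]] = 1.0
        ok, offsets = antiphase_check(traj)
        assert ok is None and offsets == []

    def test_model_baseline_interleaves(self, baseline_t2):
        ok, offsets = antiphase_check(baseline_t2, window=(2000.0, 3000.0))
        assert ok is True
        assert all(0.0 < o < 1.0 for o in offsets)


class TestClassifyFate:
    def test_baseline_is_oscillatory_progenitor(self, baseline_t2):
        assert (
            classify_fate(baseline_t2, (2000.0, 3000.0))
            is FateLabel.oscillatory_progenitor
        )

    def test_baseline_label_robust_to_initial_conditions(self, model_t2):
        for scale in (0.1, 10.0):
            traj = model_t2.simulate(3000.0, initial=np.full(N_SPECIES, 0.1 * scale))
            assert (
                classify_fate(traj, (2000.0, 3000.0))
                is FateLabel.oscillatory_progenitor
            )

    def test_differentiated_state_recognised(self):
        """Flat, Mash1-dominant, low-Hes1 trajectory classifies as
        differentiated against a higher baseline."""
        hes1 = TraceSpec(mean=1.0, amplitude=0.0, duration=1500.0)
        traj = generate_paired_network_mimic(hes1, dominance_ratio=0.2)  # Mash1 = 5x
        fate = classify_fate(traj, baseline_hes1_mean=6.0)
        assert fate is FateLabel.differentiated

    def test_damped_transition_recognised(self):
        hes1 = TraceSpec(mean=5.0, amplitude=2.0, damping=2e-3, duration=2000.0)
        mash1 = TraceSpec(
            mean=2.5, amplitude=1.0, damping=2e-3, phase=0.5, duration=2000.0, seed=1
        )
        traj = generate_paired_network_mimic(hes1, spec_mash1=mash1)
        # early window: oscillation alive but shrinking between halves
        fate = classify_fate(traj, (0.0, 1400.0), baseline_hes1_mean=5.0)
        assert fate in (FateLabel.dampened_transition, FateLabel.oscillatory_progenitor)
        # by construction the amplitude decays ~16x over the run
        late = oscillation_features(traj, "hes1_prot_nuc", (1500.0, 2000.0))
        assert late.relative_amplitude < 0.15


class TestReturnToRestLag:
    def test_empty_protocol_means_no_lag(self, baseline_t2, baseline_features_t2):
        lag = return_to_rest_lag(baseline_t2, baseline_features_t2["mash1"], 0.0)
        assert lag == 0.0

    def test_never_recovering_trace_gives_inf(self, baseline_features_t2):
        flat = generate_paired_network_mimic(
            TraceSpec(mean=1.0, amplitude=0.0, duration=3000.0)
        )
        lag = return_to_rest_lag(flat, baseline_features_t2["mash1"], 100.0)
        assert lag == math.inf


class TestPhasePlane:
    def test_constant_trajectory_is_single_point(self):
        traj = generate_paired_network_mimic(
            TraceSpec(mean=2.0, amplitude=0.0, duration=1000.0)
        )
        pts, closed = phase_plane(traj, "hes1_mrna_nuc", "hes1_prot_nuc")
        assert not closed
        assert np.ptp(pts, axis=0) == pytest.approx([0.0, 0.0])

    def test_limit_cycle_flags_closed_loop(self, baseline_t2):
        pts, closed = phase_plane(
            baseline_t2, "hes1_mrna_nuc", "hes1_prot_nuc", (2000.0, 3000.0)
        )
        assert closed
        assert pts.shape[1] == 2

    def test_damped_spiral_not_closed(self):
        traj = _trajectory_from_trace(TraceSpec(damping=3e-3, duration=3000.0))
        _, closed = phase_plane(
            traj, "hes1_mrna_nuc", "hes1_prot_nuc", (2000.0, 3000.0)
        )
        assert not closed
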