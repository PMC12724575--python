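"""Semi-Markov locomotion generator: fixed points, occupancy, determinism."""

import numpy as np
import pytest

import velozones as vz
from velozones.simulate import ModelValidationError

from conftest import four_state_model


def single_state(mean=2.0, sd=0.0, **kw):
    return vz.LocomotionModel(
        state_means=[mean], state_sds=[sd], dwell_mean_s=[4.0],
        transition_weights=[[0.0]], **kw,
    )


class TestSimulateTrace:
    def test_noise_free_fixed_point(self):
        """A noise-free single state ramps from 0 at the acceleration limit,
        then sits exactly on the state target."""
        t = vz.simulate_trace(single_state(2.0, a_max=6.0), 10.0, seed=3)
        assert len(t) == 100
        v = t.velocities
        # burn-in: 0.6 m/s per step from standing
        assert np.allclose(v[:3], [0.6, 1.2, 1.8])
        assert np.all(v[3:] == 2.0)

    def test_seeded_determinism(self, model4):
        a = vz.simulate_trace(model4, 60.0, seed=42)
        b = vz.simulate_trace(model4, 60.0, seed=42)
        assert np.array_equal(a.velocities, b.velocities)
        c = vz.simulate_trace(model4, 60.0, seed=43)
        assert not np.array_equal(a.velocities, c.velocities)

    def test_sample_count_and_time_grid(self, trace4):
        assert len(trace4) == 12000
        assert trace4.is_uniform
        assert trace4.times[0] == 0.0

    def test_acceleration_limit_and_cap(self, model4):
        t = vz.simulate_trace(model4, 300.0, seed=5)
        assert np.all(t.velocities >= 0)
        assert np.all(t.velocities <= model4.v_cap)
        dv = np.abs(np.diff(t.velocities))
        assert np.all(dv <= model4.a_max / model4.sample_hz + 1e-9)

    def test_spikes_exceed_cap(self):
        m = four_state_model(spike_rate=0.02)
        t = vz.simulate_trace(m, 600.0, seed=9)
        spikes = t.velocities[t.velocities > m.v_cap]
        assert 60 < len(spikes) < 180  # ~2% of 6000 samples
        assert np.all(spikes <= m.v_cap + 3.0)

    def test_noise_free_distance_recovers_v_times_t(self):
        """Total rectangle-rule distance equals v*T once the standing-start
        ramp is corrected for."""
        t = vz.simulate_trace(single_state(2.0, a_max=6.0), 100.0, seed=0)
        dist = t.velocities.sum() / t.sample_hz
        # ramp samples 0.6, 1.2, 1.8 undercount by (2.0*3 - 3.6)/10 m
        assert dist == pytest.approx(2.0 * 100.0 - 0.24, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(duration=0.0),
        dict(duration=-5.0),
    ])
    def test_nonpositive_duration_rejected(self, model4, bad):
        with pytest.raises(ModelValidationError):
            vz.simulate_trace(model4, bad["duration"], seed=1)

    def test_invalid_models_rejected(self):
        with pytest.raises(ModelValidationError):
            four_state_model(means=(3.0, 1.0, 5.0, 7.0))  # not increasing
        with pytest.raises(ModelValidationError):
            four_state_model(spike_rate=1.0)
        with pytest.raises(ModelValidationError):
            vz.LocomotionModel(state_means=[1, 3], state_sds=0.1, dwell_mean_s=-1,
                               transition_weights=[[0, 1], [1, 0]])
        with pytest.raises(ModelValidationError):
            vz.LocomotionModel(state_means=[1, 3], state_sds=0.1, dwell_mean_s=4,
                               transition_weights=[[0, 0], [1, 0]])  # zero row sum


class TestExpectedOccupancy:
    def test_symmetric_two_state(self):
        m = vz.LocomotionModel(state_means=[1, 3], state_sds=0.1, dwell_mean_s=4.0,
                               transition_weights=[[0, 1], [1, 0]])
        assert np.allclose(vz.expected_state_occupancy(m), [0.5, 0.5])

    def test_dwell_weighted_two_state(self):
        """Equal jump rates but dwell 2 s vs 6 s: occupancy follows dwell.

        Oracle: the embedded chain's stationary vector is (0.5, 0.5) by
        symmetry; dwell weighting gives (0.5*2, 0.5*6) normalised = (0.25, 0.75).
        """
        m = vz.LocomotionModel(state_means=[1, 3], state_sds=0.1,
                               dwell_mean_s=[2.0, 6.0],
                               transition_weights=[[0, 1], [1, 0]])
        assert np.allclose(vz.expected_state_occupancy(m), [0.25, 0.75])

    def test_symmetric_four_state(self, model4):
        assert np.allclose(vz.expected_state_occupancy(model4), 0.25)

    def test_asymmetric_weights_against_linear_solve(self):
        """Direct stationary-vector solve on a hand-built 3-state chain."""
        w = np.array([[0, 2, 1], [1, 0, 3], [4, 1, 0]], float)
        m = vz.LocomotionModel(state_means=[1, 3, 5], state_sds=0.1,
                               dwell_mean_s=[1.0, 2.0, 3.0], transition_weights=w)
        P = w / w.sum(axis=1, keepdims=True)
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        pi /= pi.sum()
        expect = pi * np.array([1.0, 2.0, 3.0])
        expect /= expect.sum()
        assert np.allclose(vz.expected_state_occupancy(m), expect)

    def test_reducible_chain_rejected(self):
        w = np.array([[0, 1, 0], [1, 0, 0], [0, 1, 0]], float)  # state 2 unreachable
        m = vz.LocomotionModel(state_means=[1, 3, 5], state_sds=0.1, dwell_mean_s=4.0,
                               transition_weights=w)
        with pytest.raises(ModelValidationError):
            vz.expected_state_occupancy(m)

    def test_empirical_occupancy_converges(self, model4):
        """30-minute trace occupancy matches the stationary law within 3 MC SEs
        (effective replicates = number of dwell segments)."""
        t = vz.simulate_trace(model4, 1800.0, seed=21)
        # assign each sample to its nearest state mean (gaps >> sd)
        states = np.argmin(np.abs(t.velocities[:, None] - model4.state_means), axis=1)
        frac = np.bincount(states, minlength=4) / len(states)
        n_segments = 1800.0 / 4.0  # mean dwell 4 s
        se = np.sqrt(0.25 * 0.75 / n_segments)
        assert np.all(np.abs(frac - 0.25) < 3 * se)
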