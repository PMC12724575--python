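"""Semi-Markov locomotion simulator for 10 Hz velocity traces.

Team-sport locomotion alternates between bouts of roughly stationary
intensity (standing, jogging, striding, sprinting).  The generator models
this as a semi-Markov chain over a small set of locomotor states: dwell
times are geometric with a per-state mean, the next state is drawn from a
row of relative transition propensities, and within a state the velocity
relaxes towards the state's target with Gaussian noise, subject to a hard
acceleration limit and a velocity cap.  Occasional samples are replaced by
artefactual spikes above the cap to emulate GPS error, which is what the
downstream cleaning rules target.

The simulator exists so that the full threshold-derivation pipeline can be
exercised and validated without access to proprietary match files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import VelocityTrace

__all__ = [
    "LocomotionModel",
    "ModelValidationError",
    "simulate_trace",
    "expected_state_occupancy",
    "simulate_cohort",
]


class ModelValidationError(ValueError):
    """A locomotion model violates its parameter constraints."""


@dataclass(frozen=True)
class LocomotionModel:
    """Parameters of the semi-Markov locomotor model.

    Attributes
    ----------
    state_means : array
        Target velocity of each state (m/s), strictly increasing, < v_cap.
    state_sds : array
        Within-state velocity noise SD per state (m/s).
    dwell_mean_s : array
        Mean dwell time per state (s); dwell is geometric in samples.
    transition_weights : array
        Square table of relative transition propensities, zero diagonal.
    a_max : float
        Maximum absolute acceleration (m/s^2); per-step velocity change is
        clipped to a_max / sample_hz.
    v_cap : float
        Hard velocity cap (m/s); genuine dynamics never exceed it.
    spike_rate : float
        Per-sample probability that the recorded value is replaced by an
        artefactual spike drawn uniformly in (v_cap, v_cap + 3].
    sample_hz : float
        Sampling rate (Hz).
    """

    state_means: np.ndarray
    state_sds: np.ndarray
    dwell_mean_s: np.ndarray
    transition_weights: np.ndarray
    a_max: float = 6.0
    v_cap: float = 10.0
    spike_rate: float = 0.0
    sample_hz: float = 10.0

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.state_means, dtype=float))
        s = np.broadcast_to(np.asarray(self.state_sds, dtype=float), m.shape).copy()
        d = np.broadcast_to(np.asarray(self.dwell_mean_s, dtype=float), m.shape).copy()
        w = np.asarray(self.transition_weights, dtype=float)
        object.__setattr__(self, "state_means", m)
        object.__setattr__(self, "state_sds", s)
        object.__setattr__(self, "dwell_mean_s", d)
        object.__setattr__(self, "transition_weights", w)
        self.validate()

    def validate(self) -> None:
        m, s, d, w = self.state_means, self.state_sds, self.dwell_mean_s, self.transition_weights
        n = len(m)
        if n == 0:
            raise ModelValidationError("at least one state required")
        if np.any(m < 0) or np.any(m >= self.v_cap):
            raise ModelValidationError("state_means must satisfy 0 <= mean < v_cap")
        if n > 1 and np.any(np.diff(m) <= 0):
            raise ModelValidationError("state_means must be strictly increasing")
        if np.any(s < 0):
            raise ModelValidationError("state_sds must be non-negative")
        if np.any(d <= 0):
            raise ModelValidationError("dwell_mean_s must be positive")
        if self.a_max <= 0:
            raise ModelValidationError("a_max must be positive")
        if not (0.0 <= self.spike_rate < 1.0):
            raise ModelValidationError("spike_rate must be in [0, 1)")
        if self.sample_hz <= 0:
            raise ModelValidationError("sample_hz must be positive")
        if n > 1:
            if w.shape != (n, n):
                raise ModelValidationError("transition_weights must be n_states x n_states")
            if np.any(w < 0) or np.any(np.diag(w) != 0):
                raise ModelValidationError("transition_weights must be non-negative, diagonal zero")
            if np.any(w.sum(axis=1) <= 0):
                raise ModelValidationError("every transition_weights row must have positive sum")

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    def embedded_transition_matrix(self) -> np.ndarray:
        """Row-normalised jump-chain transition matrix."""
        if self.n_states == 1:
            return np.ones((1, 1))
        w = self.transition_weights
        return w / w.sum(axis=1, keepdims=True)


def expected_state_occupancy(model: LocomotionModel) -> np.ndarray:
    """Stationary time fraction spent in each state.

    The embedded jump chain's stationary vector, weighted by mean dwell
    times and normalised to sum to one.  Raises for a reducible transition
    structure (the stationary distribution would not be unique).
    """
    if model.n_states == 1:
        return np.ones(1)
    P = model.embedded_transition_matrix()
    # irreducibility check via strongly connected components of the jump graph
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(P > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ModelValidationError("transition structure is reducible; occupancy undefined")
    # stationary vector: left eigenvector of P, via the unit-eigenvalue null space
    A = np.vstack([P.T - np.eye(model.n_states), np.ones(model.n_states)])
    b = np.zeros(model.n_states + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    occ = pi * model.dwell_mean_s
    return occ / occ.sum()


def simulate_trace(
    model: LocomotionModel,
    duration_s: float,
    seed: int,
    player_id: str = "p0",
    match_id: str = "m0",
    sex: str = "other",
) -> VelocityTrace:
    """Simulate one match trace of ``round(duration_s * sample_hz)`` samples.

    The state path is semi-Markov (geometric dwells, weighted jumps from
    the stationary start state); velocity starts at 0 m/s (kick-off from
    standing) and each step proposes the state target plus Gaussian noise,
    with the realised change clipped to +/- a_max/sample_hz and the result
    clamped to [0, v_cap].  With probability ``spike_rate`` a sample's
    recorded value is replaced by a uniform spike in (v_cap, v_cap + 3].
    Identical (model, duration, seed) gives an identical trace.
    """
    if duration_s <= 0:
        raise ModelValidationError("duration_s must be positive")
    model.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * model.sample_hz))
    dt = 1.0 / model.sample_hz

    # state path
    occ = expected_state_occupancy(model) if model.n_states > 1 else np.ones(1)
    P = model.embedded_transition_matrix()
    p_leave = np.minimum(1.0, 1.0 / (model.dwell_mean_s * model.sample_hz))
    states = np.empty(n, dtype=np.intp)
    s = rng.choice(model.n_states, p=occ)
    i = 0
    while i < n:
        dwell = rng.geometric(p_leave[s]) if model.n_states > 1 else n - i
        j = min(n, i + dwell)
        states[i:j] = s
        i = j
        if model.n_states > 1:
            s = rng.choice(model.n_states, p=P[s])

    # velocity path: full pull to the state target each step, accel-clipped
    noise = rng.standard_normal(n) * model.state_sds[states]
    targets = model.state_means[states] + noise
    dv_max = model.a_max * dt
    v = np.empty(n)
    prev = 0.0
    for k in range(n):
        step = targets[k] - prev
        if step > dv_max:
            step = dv_max
        elif step < -dv_max:
            step = -dv_max
        prev += step
        if prev < 0.0:
            prev = 0.0
        elif prev > model.v_cap:
            prev = model.v_cap
        v[k] = prev

    if model.spike_rate > 0:
        mask = rng.random(n) < model.spike_rate
        n_spikes = int(mask.sum())
        if n_spikes:
            v = v.copy()
            v[mask] = model.v_cap + rng.uniform(0.0, 3.0, size=n_spikes)
            # uniform in (v_cap, v_cap + 3]: shift the open endpoint
            v[mask] = np.where(v[mask] == model.v_cap, model.v_cap + 3.0, v[mask])

    times = np.arange(n) * dt
    return VelocityTrace(
        player_id=player_id, match_id=match_id, sex=sex,
        sample_hz=model.sample_hz, times=times, velocities=v,
    )


def simulate_cohort(
    model: LocomotionModel,
    n_traces: int,
    duration_s: float,
    seed: int,
    sex: str = "other",
    player_ids: list[str] | None = None,
) -> list[VelocityTrace]:
    """Simulate ``n_traces`` independent match traces with derived seeds."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_traces)]
    traces = []
    for i, cs in enumerate(child_seeds):
        pid = player_ids[i] if player_ids is not None else f"{sex[0]}{i % max(1, n_traces // 3):02d}"
        traces.append(
            simulate_trace(model, duration_s, cs, player_id=pid, match_id=f"match{i:03d}", sex=sex)
        )
    return traces
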