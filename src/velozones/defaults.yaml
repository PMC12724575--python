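# Default pipeline configuration and synthetic-cohort locomotion models.
grid:
  v_min: 0.0
  v_max: 10.0
  width: 0.1
beta: 0.1
k_mode: auto        # "auto" or a fixed integer
k_range: [2, 10]
seed: 20230021
cleaning:
  spike_cutoff: 10.0
  max_removed_fraction: 0.03
generic_scheme:
  boundaries: [2.0, 3.5, 5.5, 6.0]
  zone_names: [standing_walking, jogging, cruising, high_speed_running, sprinting]
alpha_norm: 0.05
holm: false

# Semi-Markov locomotion models for synthetic cohorts.  State means are
# calibrated so simulated maximum velocities land near the 7.4 / 8.3 m/s
# typical of elite female / male rugby sevens players.
locomotion_models:
  female:
    state_means: [1.0, 3.0, 5.0, 7.0]
    state_sds: [0.3, 0.3, 0.3, 0.3]
    dwell_mean_s: [4.0, 4.0, 4.0, 4.0]
    transition_weights:
      - [0, 1, 1, 1]
      - [1, 0, 1, 1]
      - [1, 1, 0, 1]
      - [1, 1, 1, 0]
    a_max: 6.0
    v_cap: 10.0
    spike_rate: 0.0
    sample_hz: 10.0
  male:
    state_means: [1.2, 3.2, 5.8, 7.8]
    state_sds: [0.3, 0.3, 0.3, 0.3]
    dwell_mean_s: [4.0, 4.0, 4.0, 4.0]
    transition_weights:
      - [0, 1, 1, 1]
      - [1, 0, 1, 1]
      - [1, 1, 0, 1]
      - [1, 1, 1, 0]
    a_max: 6.0
    v_cap: 10.0
    spike_rate: 0.0
    sample_hz: 10.0

simulation:
  duration_s: 1020    # ~17 min of effective play, the middle of 14-20 min
  spike_rate: 0.002   # occasional GPS artefacts to exercise the cleaning rules
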