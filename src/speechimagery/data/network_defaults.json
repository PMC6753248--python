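{
  "leak_strength": 0.30,
  "inhibition_strength": 0.15,
  "firing_threshold": 0.15,
  "depletion_rate": 0.324,
  "recovery_rate": 0.022,
  "tau_sensory": 0.031,
  "tau_phonological": 0.01,
  "weight_same": 1.0,
  "weight_cross": 0.22,
  "excitatory_reversal": 1.0,
  "inhibitory_reversal": 0.0,
  "leak_reversal": 0.0,
  "step_size": 1.0,
  "sim_duration": 800.0
}
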