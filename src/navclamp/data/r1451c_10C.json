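{
  "name": "R1451C",
  "temperature": 10.0,
  "act_v12": -16.5,
  "act_k": -10.6,
  "inact_v12": -86.4,
  "inact_k": 10.0,
  "tau_h_anchor": 0.78,
  "tau_h_shape": {
    "floor_ms": 0.2,
    "amp_ms": null,
    "efold_mV": 15.0
  },
  "tau_m": 0.1,
  "rec_fast_tau": 4.3,
  "slow_entry": {
    "tau_fast": 36.0,
    "a_fast": 0.1,
    "tau_slow": 4193.0,
    "y0": 0.25
  },
  "slow_rec_4s": {
    "tau_fast": 4.2,
    "a_fast": 0.43,
    "tau_slow": 291.0
  },
  "slow_rec_30s": {
    "tau_fast": 59.0,
    "a_fast": 0.54,
    "tau_slow": 726.0
  },
  "Ea": 22.9,
  "density": 257.0,
  "pedestal_C": 0.0
}
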