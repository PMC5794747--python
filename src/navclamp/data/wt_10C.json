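{
  "name": "WT",
  "temperature": 10.0,
  "act_v12": -22.5,
  "act_k": -8.4,
  "inact_v12": -79.7,
  "inact_k": 5.7,
  "tau_h_anchor": 0.46,
  "tau_h_shape": {
    "floor_ms": 0.2,
    "amp_ms": null,
    "efold_mV": 15.0
  },
  "tau_m": 0.1,
  "rec_fast_tau": 4.4,
  "slow_entry": {
    "tau_fast": 39.0,
    "a_fast": 0.064,
    "tau_slow": 3810.0,
    "y0": 0.25
  },
  "slow_rec_4s": {
    "tau_fast": 3.3,
    "a_fast": 0.47,
    "tau_slow": 243.0
  },
  "slow_rec_30s": {
    "tau_fast": 24.0,
    "a_fast": 0.46,
    "tau_slow": 382.0
  },
  "Ea": 19.9,
  "density": 699.3,
  "pedestal_C": 0.0
}
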