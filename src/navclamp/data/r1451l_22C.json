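{
  "name": "R1451L",
  "temperature": 22.0,
  "act_v12": -30.7,
  "act_k": -7.9,
  "inact_v12": -91.8,
  "inact_k": 9.4,
  "tau_h_anchor": 0.99,
  "tau_h_shape": {
    "floor_ms": 0.2,
    "amp_ms": null,
    "efold_mV": 15.0
  },
  "tau_m": 0.1,
  "rec_fast_tau": 1.3,
  "slow_entry": {
    "tau_fast": 38.0,
    "a_fast": 0.079,
    "tau_slow": 3085.0,
    "y0": 0.25
  },
  "slow_rec_4s": {
    "tau_fast": 2.0,
    "a_fast": 0.41,
    "tau_slow": 420.0
  },
  "slow_rec_30s": {
    "tau_fast": 162.0,
    "a_fast": 0.41,
    "tau_slow": 1978.0
  },
  "Ea": 21.3,
  "density": 374.5,
  "pedestal_C": 0.0
}
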