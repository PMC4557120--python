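{
  "rank": 0,
  "singular_values": [
    3.6055512754639896
  ],
  "diagnostics": [
    {
      "component": 0,
      "singular_value": 3.6055512754639896,
      "u_autocorr": 1.0,
      "v_autocorr": 1.0,
      "noise_floor": 3.6055512754639896,
      "significant": false,
      "rationale": "sv < 5.0\u00d7floor(3.61); autocorr \u2265 0.8"
    }
  ]
}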