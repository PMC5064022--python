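{
  "name": "iks-6state-drug-free",
  "constants": {"F": 96485.33212, "R": 8.31446261815324, "T": 293.15},
  "states": [
    {"label": "C1", "conducting": false},
    {"label": "C2", "conducting": false},
    {"label": "C3", "conducting": false},
    {"label": "O1", "conducting": true},
    {"label": "O2", "conducting": true},
    {"label": "C2s", "conducting": false}
  ],
  "transitions": [
    {"source": "C1", "target": "C2", "amplitude": 1.0, "charge": 0.47},
    {"source": "C2", "target": "C1", "amplitude": 0.2, "charge": -0.35},
    {"source": "C2", "target": "C3", "amplitude": 0.46, "charge": 0.47},
    {"source": "C3", "target": "C2", "amplitude": 3.3, "charge": -0.35},
    {"source": "C3", "target": "O1", "amplitude": 24.0, "charge": 0.06},
    {"source": "O1", "target": "C3", "amplitude": 19.0, "charge": -0.007},
    {"source": "O1", "target": "O2", "amplitude": 4.6, "charge": 0.8},
    {"source": "O2", "target": "O1", "amplitude": 1.4, "charge": -0.7},
    {"source": "C2", "target": "C2s", "amplitude": 10.0, "charge": 0.0},
    {"source": "C2s", "target": "C2", "amplitude": 10.0, "charge": 0.0}
  ]
}
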