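name: cuboid_Q1NC_h0.8
geometry:
  dimensions:
  - 20.0
  - 7.0
  - 3.0
  h: 0.8
family: Q1NC
conductivity:
  d_l: 0.0952
  d_t: 0.0126
  fiber:
  - 1.0
  - 0.0
  - 0.0
ionic:
  alpha: 0.05
  c1: 52.0
  c2: 8.0
  mu1: 0.1
  mu2: 0.3
  b: 0.25
  gamma: 0.002
  Vr: -85.0
  Vp: 15.0
  r0: 0.1146
  time_scale: 12.9
time:
  scheme: SI
  dt: 0.02
  t_end: 150.0
  newton_tol: 1.0e-10
  newton_max_iter: 25
  snapshot_every_ms: null
stimuli:
- kind: volume
  amplitude: 0.35714285714285715
  start: 0.0
  duration: 2.0
  box:
  - - 0.0
    - 1.5
  - - 0.0
    - 1.5
  - - 0.0
    - 1.5
  face_set: null
probes:
- - 0.0
  - 0.0
  - 0.0
- - 20.0
  - 7.0
  - 3.0
threshold: 0.5
stop_when: all_activated
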