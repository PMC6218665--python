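name: rod_Q1_SI_h0.5
geometry:
  dimensions:
  - 25.0
  - 0.5
  - 0.5
  h: 0.5
family: Q1
conductivity:
  d_l: 0.0952
  d_t: 0.0952
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
  dt: 0.005
  t_end: 150.0
  newton_tol: 1.0e-10
  newton_max_iter: 25
  snapshot_every_ms: null
stimuli:
- kind: volume
  amplitude: 0.2
  start: 0.0
  duration: 2.0
  box:
  - - 0.0
    - 1.0
  - - 0.0
    - 0.5
  - - 0.0
    - 0.5
  face_set: null
probes:
- - 18.0
  - 0.0
  - 0.0
- - 22.0
  - 0.0
  - 0.0
threshold: 0.5
stop_when: probes_activated
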