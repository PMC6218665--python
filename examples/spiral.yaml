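name: spiral_Q1NC_h1
geometry:
  dimensions:
  - 50.0
  - 50.0
  - 1.0
  h: 1.0
family: Q1NC
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
  t_end: 600.0
  newton_tol: 1.0e-10
  newton_max_iter: 25
  snapshot_every_ms: 10.0
stimuli:
- kind: surface
  amplitude: 0.12
  start: 0.0
  duration: 2.0
  box: null
  face_set: xmin
- kind: volume
  amplitude: 0.15
  start: 280.0
  duration: 5.0
  box:
  - - 0.0
    - 25.0
  - - 0.0
    - 25.0
  - - 0.0
    - 1.0
  face_set: null
probes:
- - 12.5
  - 12.5
  - 0.0
- - 37.5
  - 37.5
  - 0.0
threshold: 0.5
stop_when: t_end
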