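# Scenario 2: median characteristics of completed SW-CRTs (20 clusters, 9 periods,
# near-balanced stepping 3,3,3,3,2,2,2,2; ICC 0.1).
C: 20
T: 9
schedule: [3, 3, 3, 3, 2, 2, 2, 2]
sigma_c2: 0.1111111111111111
sigma_e2: 1.0
alpha: 0.05
beta: 0.2
delta: 0.24
designs:
  - {label: design1, analyses: [2, 4, 7, 9], mode: both,     gamma_e: 0.5, gamma_f: 0.5, m: search}
  - {label: design2, analyses: [5, 9],       mode: futility,               gamma_f: 1.0, m: search}
  - {label: design3, analyses: [3, 6, 9],    mode: efficacy, gamma_e: 1.0,               m: search}
  - {label: design4, analyses: [2, 4, 7, 9], mode: both,     gamma_e: 1.5, gamma_f: 1.0, m: search}
  - {label: design5, analyses: [5, 9],       mode: futility,               gamma_f: 1.5, m: search}
  - {label: design6, analyses: [3, 6, 9],    mode: efficacy, gamma_e: 0.5,               m: search}
  - {label: design7, analyses: [9],          mode: none,                                 m: search}
simulate:
  design: design1
  method: REML
  adjust: false
  assumed_scale: 1.0
  tau_true: 0.0
  n_reps: 10000
  seed: 0
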