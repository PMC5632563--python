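# Scenario 1: communication-skills training SW-CRT (4 hospitals, 5 periods).
C: 4
T: 5
sigma_c2: 0.02
sigma_e2: 0.51
alpha: 0.05
beta: 0.1
delta: 0.2
designs:
  - {label: design1, analyses: [2, 3, 4, 5], mode: both,     gamma_e: 0.5, gamma_f: 0.5, m: search}
  - {label: design2, analyses: [3, 5],       mode: futility,               gamma_f: 1.0, m: search}
  - {label: design3, analyses: [3, 4, 5],    mode: efficacy, gamma_e: 1.0,               m: search}
  - {label: design4, analyses: [2, 3, 4, 5], mode: both,     gamma_e: 1.5, gamma_f: 1.0, m: search}
  - {label: design5, analyses: [3, 5],       mode: futility,               gamma_f: 1.5, m: search}
  - {label: design6, analyses: [3, 4, 5],    mode: efficacy, gamma_e: 0.5,               m: search}
  - {label: design7, analyses: [5],          mode: none,                                 m: search}
simulate:
  design: design1
  method: REML
  adjust: false
  assumed_scale: 1.0
  tau_true: 0.0
  n_reps: 10000
  seed: 0
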