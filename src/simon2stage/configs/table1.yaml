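# Monte Carlo study over the four 90%-power designs with one-sided
# nominal level 0.10 (Simon optimal designs for effect sizes 0.2->0.4,
# 0.3->0.5, 0.4->0.6, 0.5->0.7).  The realized stage-2 size of each
# continuing trial is uniform on ceil(n2/3)..floor(1.5*n2).
designs:
  - {id: design1, r1: 3, n1: 17, rt: 10, nt: 37, pi0: 0.2, pi1: 0.4}
  - {id: design2, r1: 7, n1: 22, rt: 17, nt: 46, pi0: 0.3, pi1: 0.5}
  - {id: design3, r1: 7, n1: 18, rt: 22, nt: 46, pi0: 0.4, pi1: 0.6}
  - {id: design4, r1: 11, n1: 21, rt: 26, nt: 45, pi0: 0.5, pi1: 0.7}
pi_grid: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
reps: 5000
level: 0.90
alpha_test: 0.05
seed: 20150607
methods: [LR, KC]
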