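# Reference parameter set of the branching model (dimensionless units).
c: 0.002
mu: 0.16
rho_A: 0.03
D_A: 0.02
v: 0.04
rho_H: 0.0001
D_H: 0.3
c0: 0.02
gamma: 0.02
epsilon: 1.0
D_S: 0.06
d: 0.008
e: 0.1
f: 10.0
kappa: 0.0
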