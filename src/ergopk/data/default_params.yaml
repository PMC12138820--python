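R: 1.36
k_a: 6.0
V_p: 3.0
V_RBC: 2.29
V_a: 10.0
V_ae: 2.0
V_h: 1.69
V_he: 0.338
V_s: 7.8
V_se: 1.56
V_m: 35.0
V_me: 7.0
V_d: 0.127
Q_a: 8.74
Q_h: 48.7
Q_s: 18.0
Q_m: 45.0
Q_u: 0.0583
GFR: 7.5
k_1: 0.0104
k_b: 0.000963
V_maxH: 10227.0
V_maxD: 121.0
V_maxP: 11.1
K_m: 21.0
K_pH: 80.1
K_pM: 5.06
K_pA: 17.5
K_pS: 20.8
e_H: 0.147
e_M: 0.464
e_A: 0.209
e_S: 0.131
Hct: 0.4403846153846154
n_liver_units: 5
absorption_route: portal
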