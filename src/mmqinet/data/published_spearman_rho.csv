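,Vt-PET,Vt-MRI,ADC,D,D*,f,Ktrans,ve,tau_i,kep,SULmax,SULmean,K1,k3max,k3mean,DV,TBRmax,TBRmean
Vt-PET,1,0.84,-0.09,-0.1,0.28,-0.06,0.19,-0.09,0.16,0.17,0.58,0.42,0.26,0.29,0.13,0.16,0.3,0.2
Vt-MRI,0.84,1,-0.17,-0.18,0.07,0.01,0.14,-0.14,0.12,0.26,0.57,0.48,0.17,0.3,0.31,0.04,0.25,0.27
ADC,-0.09,-0.17,1,0.95,-0.34,-0.18,-0.48,0.46,-0.36,0.18,-0.29,-0.42,-0.4,0.26,0.15,-0.31,0.07,-0.14
D,-0.1,-0.18,0.95,1,-0.26,-0.18,-0.43,0.32,-0.41,0.23,-0.31,-0.41,-0.4,0.32,0.23,-0.32,0.14,-0.08
D*,0.28,0.07,-0.34,-0.26,1,0.39,0.39,-0.11,0.01,0.04,0.21,0.24,0.4,-0.25,-0.35,0.49,0.09,0.13
f,-0.06,0.01,-0.18,-0.18,0.39,1,0.31,0.18,0.14,-0.14,0.06,0.2,0.2,-0.45,-0.3,0.4,-0.18,0.12
Ktrans,0.19,0.14,-0.48,-0.43,0.39,0.31,1,-0.1,0.43,0.12,0.17,0.28,0.48,-0.41,-0.27,0.44,-0.17,-0.03
ve,-0.09,-0.14,0.46,0.32,-0.11,0.18,-0.1,1,-0.41,-0.15,0.17,0.15,0.02,-0.2,-0.26,0.4,0.14,0.13
tau_i,0.16,0.12,-0.36,-0.41,0.01,0.14,0.43,-0.41,1,-0.03,0.06,0.11,0.08,-0.17,0.05,-0.04,-0.23,-0.12
kep,0.17,0.26,0.18,0.23,0.04,-0.14,0.12,-0.15,-0.03,1,-0.11,-0.16,0.2,0.34,0.2,-0.23,-0.09,-0.2
SULmax,0.58,0.57,-0.29,-0.31,0.21,0.06,0.17,0.17,0.06,-0.11,1,0.94,-0.01,-0.09,-0.02,0.42,0.36,0.44
SULmean,0.42,0.48,-0.42,-0.41,0.24,0.2,0.28,0.15,0.11,-0.16,0.94,1,0.003,-0.15,-0.02,0.48,0.38,0.53
K1,0.26,0.17,-0.4,-0.4,0.4,0.2,0.48,0.02,0.08,0.2,-0.01,0.003,1,-0.26,-0.46,0.59,-0.18,-0.19
k3max,0.29,0.3,0.26,0.32,-0.25,-0.45,-0.41,-0.2,-0.17,0.34,-0.09,-0.15,-0.26,1,0.79,-0.57,0.57,0.34
k3mean,0.13,0.31,0.15,0.23,-0.35,-0.3,-0.27,-0.26,0.05,0.2,-0.02,-0.02,-0.46,0.79,1,-0.6,0.57,0.54
DV,0.16,0.04,-0.31,-0.32,0.49,0.4,0.44,0.4,-0.04,-0.23,0.42,0.48,0.59,-0.57,-0.6,1,0.13,0.23
TBRmax,0.3,0.25,0.07,0.14,0.09,-0.18,-0.17,0.14,-0.23,-0.09,0.36,0.38,-0.18,0.57,0.57,0.13,1,0.88
TBRmean,0.2,0.27,-0.14,-0.08,0.13,0.12,-0.03,0.13,-0.12,-0.2,0.44,0.53,-0.19,0.34,0.54,0.23,0.88,1
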