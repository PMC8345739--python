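,Vt-PET,Vt-MRI,ADC,D,D*,f,Ktrans,ve,tau_i,kep,SULmax,SULmean,K1,k3max,k3mean,DV,TBRmax,TBRmean
Vt-PET,0,1,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
Vt-MRI,1,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
ADC,0,0,0,1,0,0,1,1,0,0,0,1,1,0,0,0,0,0
D,0,0,1,0,0,0,1,0,1,0,0,1,1,0,0,0,0,0
D*,0,0,0,0,0,1,1,0,0,0,0,0,1,0,0,1,0,0
f,0,0,0,0,1,0,0,0,0,0,0,0,0,1,0,1,0,0
Ktrans,0,0,1,1,1,0,0,0,1,0,0,0,1,1,0,1,0,0
ve,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,1,0,0
tau_i,0,0,0,1,0,0,1,1,0,0,0,0,0,0,0,0,0,0
kep,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
SULmax,1,1,0,0,0,0,0,0,0,0,0,1,0,0,0,1,0,1
SULmean,1,1,1,1,0,0,0,0,0,0,1,0,0,0,0,1,0,1
K1,0,0,1,1,1,0,1,0,0,0,0,0,0,0,1,1,0,0
k3max,0,0,0,0,0,1,1,0,0,0,0,0,0,0,1,1,1,0
k3mean,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,1,1,1
DV,0,0,0,0,1,1,1,1,0,0,1,1,1,1,1,0,0,0
TBRmax,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,1
TBRmean,0,0,0,0,0,0,0,0,0,0,1,1,0,0,1,0,1,0
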