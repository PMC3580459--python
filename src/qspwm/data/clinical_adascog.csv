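drug,dose_mg,weeks,adascog_effect
Placebo,0,12,0.27
Placebo,0,26,1.87
Placebo,0,52,5.07
Placebo,0,78,7.10
Donepezil,5,12,-1.77
Donepezil,5,26,-0.27
Donepezil,5,52,2.87
Donepezil,10,12,-2.12
Donepezil,10,26,-0.64
Donepezil,10,52,2.48
Galantamine,8,12,-1.77
Galantamine,8,26,-0.95
Galantamine,8,52,1.29
Galantamine,16,12,-1.96
Galantamine,16,26,-1.10
Galantamine,16,52,1.49
Galantamine,24,12,-1.96
Galantamine,24,26,-1.10
Galantamine,24,52,1.49
Rivastigmine,6,12,-0.66
Rivastigmine,6,26,0.70
Rivastigmine,6,52,3.71
Rivastigmine,12,12,-1.82
Rivastigmine,12,26,-0.77
Rivastigmine,12,52,2.01
SB-742457,5,26,-0.22
SB-742457,15,26,-0.66
SB-742457,35,26,-1.12
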