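constituent,center_cm1,width_cm1,amplitude
lignin,4401,80,0.9
lignin,4411,80,0.8
lignin,4280,80,0.7
extractives,6913,80,0.6
extractives,7092,80,0.5
cellulose,6307,80,0.8
cellulose,5814,80,0.7
cellulose,4405,80,0.6
hemicellulose,7410,80,0.5
hemicellulose,6003,80,0.6
hemicellulose,5236,80,0.8
hemicellulose,4686,80,0.7
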