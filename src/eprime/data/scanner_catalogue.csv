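model,weight,rotation_time_s,n_sources_max,multisegment_available,fast_acquisition_frac,pixel_size_mm
Definition,20,0.33,2,1,0.67,0.40
Definition-Flash,13,0.28,2,1,0.67,0.40
Sensation-64,13,0.33,1,1,0.67,0.40
Sensation-Cardiac,5,0.37,1,1,0.67,0.42
Definition-AS,4,0.30,1,1,0.67,0.40
Definition-AS-Plus,1,0.30,1,1,0.67,0.40
LightSpeed-VCT,40,0.35,1,1,0.02,0.43
Discovery-CT750-HD,3,0.35,1,1,0.02,0.41
Discovery-STE,1,0.40,1,1,0.02,0.43
Brilliance-64,11,0.40,1,1,0.06,0.43
iCT-256,5,0.27,1,1,0.06,0.40
Aquilion-64,10,0.40,1,1,0.60,0.43
Aquilion-ONE,5,0.35,1,1,0.60,0.42
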