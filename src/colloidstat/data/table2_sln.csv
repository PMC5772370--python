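condition,pl_percent,size_nm,size_sd_nm,particles_per_ml,particles_sd,molecules_per_particle
SLN1,5,232.1,2.7,6.13e13,0.02e13,2.0e6
SLN2,3,284.2,9.9,3.36e13,0.06e13,3.7e6
SLN3,1,499.1,0.4,2.72e13,0.05e13,4.6e6
SLN4,0.25,540.9,20.5,2.33e13,0.08e13,5.4e6
SLN5,0.1,1644.3,255.9,4.8e12,0.1e12,2.6e7
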