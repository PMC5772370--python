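condition,size_nm,size_sd_nm,particles_per_ml,particles_sd,chcl3_molecules_per_ml,molecules_per_particle
chcl3_0.0,116.5,1.8,9.4e11,0.7e11,0,8.0e4
chcl3_0.5,171.8,2.3,6.4e11,0.2e11,7.2e16,11.7e4
chcl3_1.0,491.9,19.4,3.1e11,0.6e11,11.4e16,24.2e4
chcl3_2.0,657.6,17.0,2.1e11,0.1e11,15.0e16,35.7e4
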