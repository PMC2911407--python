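# E2A model parameters (flat key=value; angles rad, lengths nm)
nrl_bp = 196
wrapped_bp = 147
rise_nm_per_bp = 0.34
alpha_dist = normal:0.690834,0.2427
beta_dist = normal:2.242015,0.4854
linker_nm = 51.13
linker_sd_nm = 0.63
pitch_d_nm = 2.7
nucleosome_radius_nm = 5.5
nucleosome_height_nm = 5.5
dna_radius_nm = 1.2
p_nuc_skip = 0.08
p_lh_skip = 0.06
naked_dna_lp_nm = 50.0
naked_dna_seg_bp = 10
lh_alpha_max_rad = 3.141592653589793
lh_unwrap_bp_max = 80.0
contact_radius_nm = 35.0
analysis_cutoff_nm = 40.0
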