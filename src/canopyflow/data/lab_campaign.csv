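leaf_area_density,v_star,force_N,s_m2,R_m,D_m,D_prime_m
4.15,4,0.97,0.057,0.16,0.9,0.3
4.15,8,2.96,0.057,0.16,0.9,0.3
4.15,12,4.98,0.057,0.16,0.9,0.3
4.79,4,0.94,0.060,0.16,0.9,0.3
4.79,8,2.63,0.060,0.16,0.9,0.3
4.79,12,4.49,0.060,0.16,0.9,0.3
5.65,4,0.88,0.065,0.16,0.9,0.3
5.65,8,2.35,0.065,0.16,0.9,0.3
5.65,12,4.11,0.065,0.16,0.9,0.3
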