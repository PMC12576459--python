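hu_lo,hu_hi,material,rho_lo,rho_hi
-1024,-950,air,0.001205,0.001205
-950,-120,lung_tissue,0.050,0.880
-120,-20,adipose,0.880,0.980
-20,55,soft_tissue,0.988,1.033
55,300,soft_tissue,1.033,1.160
300,3000,bone_cortical,1.200,2.800
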