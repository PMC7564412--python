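parent,daughter,branch_fraction,alpha_energy_mev,parent_half_life_h
At-211,Bi-207,0.4180,5.8695,7.214
At-211,Po-211,0.5820,0.0,7.214
Po-211,Pb-207,1.0,7.4503,1.4333e-4
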