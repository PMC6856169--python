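class,gC_m2
forest,22.0
grassland,10.0
wetland,15.0
farmland,8.0
artificial,1.0
bare,0.5
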