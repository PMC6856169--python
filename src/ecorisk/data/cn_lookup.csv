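class,group,cn
forest,A,30
forest,B,55
forest,C,70
forest,D,77
grassland,A,39
grassland,B,61
grassland,C,74
grassland,D,80
wetland,A,85
wetland,B,87
wetland,C,89
wetland,D,91
farmland,A,67
farmland,B,78
farmland,C,85
farmland,D,89
artificial,A,89
artificial,B,92
artificial,C,94
artificial,D,95
bare,A,77
bare,B,86
bare,C,91
bare,D,94
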