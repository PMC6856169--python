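class,category,yuan_per_m2
forest,provisioning,0.40
forest,supporting,1.00
forest,regulating,2.50
forest,cultural,0.19
grassland,provisioning,0.30
grassland,supporting,0.70
grassland,regulating,1.50
grassland,cultural,0.12
wetland,provisioning,0.35
wetland,supporting,0.90
wetland,regulating,2.20
wetland,cultural,0.20
farmland,provisioning,0.42
farmland,supporting,0.60
farmland,regulating,1.00
farmland,cultural,0.10
artificial,provisioning,0.01
artificial,supporting,0.02
artificial,regulating,0.05
artificial,cultural,0.02
bare,provisioning,0.005
bare,supporting,0.01
bare,regulating,0.02
bare,cultural,0.005
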