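name,block,attribute
mean_dn,pressure,positive
artificial_ratio,pressure,positive
npp,status,positive
evi,status,positive
et,status,positive
cn,status,negative
carbon,status,positive
lcr,status,negative
esv_provisioning,response,positive
esv_supporting,response,positive
esv_regulating,response,positive
esv_cultural,response,positive
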