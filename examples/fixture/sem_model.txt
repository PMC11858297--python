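# Demo richness path model (synthetic fixture): nitrate (NN) and sodium
# (Na) suppress bacterial/fungal richness (BC/FC) directly and, for
# nitrate, indirectly via cucumber root growth (RW); ammonium (AN)
# supports root growth.
RW ~ NN + AN
BC ~ NN + Na + RW
FC ~ Na + RW
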