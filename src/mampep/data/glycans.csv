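# N-glycan compositions (residue counts; glycosidic bonds already dehydrated).
# A2Ga1G1F is the alpha-Gal positional isomer of A2G2F: identical composition and mass,
# distinguished only by retention time (rt_resolved), offset +0.8 min from its isobar.
name,Hex,HexNAc,Fuc,NeuAc,rt_resolved,rt_offset_min
M5,5,2,0,0,0,-0.55
A1G0F,3,3,1,0,0,-0.35
A2G0F,3,4,1,0,0,-0.30
A1G1F,4,3,1,0,0,-0.45
A2G1F,4,4,1,0,0,-0.40
A2G2F,5,4,1,0,0,-0.50
A2Ga1G1F,5,4,1,0,1,0.30
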