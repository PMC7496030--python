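>HC synthetic IgG1-like heavy chain (concatenated reference tryptic peptides with filler)
QVTLRESGGGLVQPGGSLRDTLMISRTPEVTCVVVDVSHEDPEVKFNWYVDGVEVHNAK
VVSVLTVLHQDWLNGKEYKCKVSNKALPAPIEKEEMTKNQVSLTCLVKGFYPSDIAVEWE
SNGQPENNYKTKPREEQYNSTYRWQQGNVFSCSVMHEALHNHYTQKSLSLSPGK
>LC synthetic kappa light chain (concatenated reference tryptic peptides with filler)
DIQMTQSPSSLSASVGDRVTITCRASQDINNYLNWYQQKPGKLLIYWASTRASQDVDTAV
AWYQQKPGKFSGSGSGTDFTLTISRVYACEVTHQGLSSPVTKSFNRGEC
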