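# Reference PTM relative abundances (%) for an IgG1 monitored in four laboratories,
# used as canonical ground-truth presets for the synthetic generator.
# sequence is the fully-cleaved tryptic peptide carrying the site; partners are the
# <=1-missed-cleavage forms whose areas are combined into the same attribute.
# site_offset is the 1-based position of the modified residue within sequence
# (semicolon-separated when the site is ambiguous and reported at peptide level).
attribute,site_label,modification,sequence,partners,site_offset,mode,Ireland,Denmark,UK,Switzerland
HC N328 + deamidation,HC N328,deamidation,VSNK,CKVSNK;VSNKALPAPIEK,3,pairwise,0.30,0.50,0.33,0.50
HC N364 + deamidation,HC N364,deamidation,NQVSLTCLVK,EEMTKNQVSLTCLVK,1,pairwise,0.37,0.20,0.29,0.05
HC ~N392/N387 + deamidation,HC ~N392/N387,deamidation,GFYPSDIAVEWESNGQPENNYK,,14;19,pairwise,0.79,0.21,0.24,0.64
HC ~N392/N387 + succinimide,HC ~N392/N387,succinimide,GFYPSDIAVEWESNGQPENNYK,,14;19,pairwise,2.06,2.27,2.73,2.60
HC N318 + succinimide,HC N318,succinimide,VVSVLTVLHQDWLNGK,VVSVLTVLHQDWLNGKEYK,14,pairwise,2.05,2.61,2.66,2.25
HC D283 + succinimide,HC D283,succinimide,FNWYVDGVEVHNAK,TPEVTCVVVDVSHEDPEVKFNWYVDGVEVHNAK,6,pairwise,2.18,3.40,1.56,3.56
HC M255 + oxidation,HC M255,oxidation,DTLMISR,,4,pairwise,1.26,1.29,1.05,0.92
HC K450 Lys loss,HC K450,Lys loss,SLSLSPGK,WQQGNVFSCSVMHEALHNHYTQKSLSLSPGK,8,pairwise,87.01,88.49,90.73,88.79
HC Q1 + Gln->PyroGlu,HC Q1,Gln->PyroGlu,QVTLR,,1,pairwise,99.29,99.31,99.75,99.32
HC N300 + M5,HC N300,M5,EEQYNSTYR,TKPREEQYNSTYR,5,profile,1.71,1.29,1.10,1.22
HC N300 + A1G0F,HC N300,A1G0F,EEQYNSTYR,TKPREEQYNSTYR,5,profile,6.05,5.04,11.26,10.95
HC N300 + A2G0F,HC N300,A2G0F,EEQYNSTYR,TKPREEQYNSTYR,5,profile,41.13,40.14,37.36,37.05
HC N300 + A1G1F,HC N300,A1G1F,EEQYNSTYR,TKPREEQYNSTYR,5,profile,4.06,3.68,5.92,6.13
HC N300 + A2G1F,HC N300,A2G1F,EEQYNSTYR,TKPREEQYNSTYR,5,profile,36.11,38.65,33.86,34.89
HC N300 + A2G2F,HC N300,A2G2F,EEQYNSTYR,TKPREEQYNSTYR,5,profile,6.92,8.49,7.02,7.31
HC N300 + A2Ga1G1F,HC N300,A2Ga1G1F,EEQYNSTYR,TKPREEQYNSTYR,5,profile,0.91,1.42,1.09,1.21
HC N300 + unglycosylated,HC N300,unglycosylated,EEQYNSTYR,TKPREEQYNSTYR,5,profile,3.06,1.29,2.39,1.25
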