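# Reference degradation series: mean relative abundance (%) and intra-lab RSD (%) of
# targeted attributes in a 6-mAb mixture stressed at 40 C, measured at two sites (A, B)
# after 0, 3 and 6 months (n = 3 digests per cell). Missing cells are absent rows.
protein,site_label,modification,sequence,site_offset,timepoint_months,site,mean,rsd
mAb4_HC,N101,deamidation,KGNYGNYGK,3,0,A,6.02,1.81
mAb4_HC,N101,deamidation,KGNYGNYGK,3,0,B,4.81,5.57
mAb4_HC,N101,deamidation,KGNYGNYGK,3,3,A,18.81,3.33
mAb4_HC,N101,deamidation,KGNYGNYGK,3,3,B,16.04,5.12
mAb4_HC,N101,deamidation,KGNYGNYGK,3,6,A,21.61,1.37
mAb4_HC,N101,deamidation,KGNYGNYGK,3,6,B,24.23,3.35
mAb6_LC,~N30,deamidation,ASQDINNYLNWYQQKPGK,6;7,0,A,1.27,7.54
mAb6_LC,~N30,deamidation,ASQDINNYLNWYQQKPGK,6;7,0,B,0.46,8.08
mAb6_LC,~N30,deamidation,ASQDINNYLNWYQQKPGK,6;7,3,A,28.08,1.14
mAb6_LC,~N30,deamidation,ASQDINNYLNWYQQKPGK,6;7,3,B,25.52,0.67
mAb6_LC,~N30,deamidation,ASQDINNYLNWYQQKPGK,6;7,6,A,44.68,1.40
mAb6_LC,~N30,deamidation,ASQDINNYLNWYQQKPGK,6;7,6,B,43.65,0.16
mAb1_HC,~N389,deamidation,GFYPSDIAVEWESNGQPENNYK,14;19,0,A,1.66,6.33
mAb1_HC,~N389,deamidation,GFYPSDIAVEWESNGQPENNYK,14;19,0,B,0.19,7.41
mAb1_HC,~N389,deamidation,GFYPSDIAVEWESNGQPENNYK,14;19,3,A,2.54,7.91
mAb1_HC,~N389,deamidation,GFYPSDIAVEWESNGQPENNYK,14;19,3,B,0.44,5.78
mAb1_HC,~N389,deamidation,GFYPSDIAVEWESNGQPENNYK,14;19,6,A,3.28,8.33
mAb1_HC,~N389,deamidation,GFYPSDIAVEWESNGQPENNYK,14;19,6,B,0.69,3.70
mAb1_HC,~N384,NH3 loss,GFYPSDIAVEWESNGQPENNYK,14;19,0,A,1.70,5.48
mAb1_HC,~N384,NH3 loss,GFYPSDIAVEWESNGQPENNYK,14;19,0,B,0.33,3.99
mAb1_HC,~N384,NH3 loss,GFYPSDIAVEWESNGQPENNYK,14;19,3,A,1.99,3.84
mAb1_HC,~N384,NH3 loss,GFYPSDIAVEWESNGQPENNYK,14;19,3,B,0.34,4.26
mAb1_HC,~N384,NH3 loss,GFYPSDIAVEWESNGQPENNYK,14;19,6,A,1.98,2.30
mAb1_HC,~N384,NH3 loss,GFYPSDIAVEWESNGQPENNYK,14;19,6,B,0.30,5.57
mAb1_HC,N315,deamidation,VVSVLTVLHQDWLNGK,14,0,A,0.96,0.52
mAb1_HC,N315,deamidation,VVSVLTVLHQDWLNGK,14,0,B,0.65,6.29
mAb1_HC,N315,deamidation,VVSVLTVLHQDWLNGK,14,3,A,1.19,4.25
mAb1_HC,N315,deamidation,VVSVLTVLHQDWLNGK,14,3,B,0.70,3.99
mAb1_HC,N315,deamidation,VVSVLTVLHQDWLNGK,14,6,A,1.48,1.88
mAb1_HC,N315,deamidation,VVSVLTVLHQDWLNGK,14,6,B,0.61,3.79
mAb1_HC,N315,NH3 loss,VVSVLTVLHQDWLNGK,14,0,A,3.89,4.69
mAb1_HC,N315,NH3 loss,VVSVLTVLHQDWLNGK,14,0,B,2.67,4.28
mAb1_HC,N315,NH3 loss,VVSVLTVLHQDWLNGK,14,3,A,4.31,3.43
mAb1_HC,N315,NH3 loss,VVSVLTVLHQDWLNGK,14,3,B,2.68,4.09
mAb1_HC,N315,NH3 loss,VVSVLTVLHQDWLNGK,14,6,A,4.59,6.29
mAb1_HC,N315,NH3 loss,VVSVLTVLHQDWLNGK,14,6,B,2.47,2.98
mAb2_LC,~D30,isomerisation,ASQDVDTAVAWYQQKPGK,4;6,0,A,3.42,3.96
mAb2_LC,~D30,isomerisation,ASQDVDTAVAWYQQKPGK,4;6,0,B,2.33,5.63
mAb2_LC,~D30,isomerisation,ASQDVDTAVAWYQQKPGK,4;6,3,A,47.75,3.63
mAb2_LC,~D30,isomerisation,ASQDVDTAVAWYQQKPGK,4;6,3,B,40.66,1.08
mAb2_LC,~D30,isomerisation,ASQDVDTAVAWYQQKPGK,4;6,6,B,45.92,1.43
mAb2_LC,~D30,H2O loss,ASQDVDTAVAWYQQKPGK,4;6,0,A,0.16,5.79
mAb2_LC,~D30,H2O loss,ASQDVDTAVAWYQQKPGK,4;6,0,B,0.13,9.86
mAb2_LC,~D30,H2O loss,ASQDVDTAVAWYQQKPGK,4;6,3,A,2.14,3.50
mAb2_LC,~D30,H2O loss,ASQDVDTAVAWYQQKPGK,4;6,3,B,2.52,2.81
mAb2_LC,~D30,H2O loss,ASQDVDTAVAWYQQKPGK,4;6,6,A,2.03,4.38
mAb2_LC,~D30,H2O loss,ASQDVDTAVAWYQQKPGK,4;6,6,B,2.83,0.48
mAb1_HC,D280,isomerisation,FNWYVDGVEVHNAK,6,0,A,0.73,6.71
mAb1_HC,D280,isomerisation,FNWYVDGVEVHNAK,6,0,B,0.57,3.32
mAb1_HC,D280,isomerisation,FNWYVDGVEVHNAK,6,3,A,6.06,2.11
mAb1_HC,D280,isomerisation,FNWYVDGVEVHNAK,6,3,B,4.71,3.71
mAb1_HC,D280,isomerisation,FNWYVDGVEVHNAK,6,6,A,9.59,2.86
mAb1_HC,D280,isomerisation,FNWYVDGVEVHNAK,6,6,B,7.74,2.55
mAb1_HC,D280,H2O loss,FNWYVDGVEVHNAK,6,0,A,0.06,3.63
mAb1_HC,D280,H2O loss,FNWYVDGVEVHNAK,6,0,B,0.22,2.97
mAb1_HC,D280,H2O loss,FNWYVDGVEVHNAK,6,3,A,0.17,4.71
mAb1_HC,D280,H2O loss,FNWYVDGVEVHNAK,6,3,B,0.37,1.11
mAb1_HC,D280,H2O loss,FNWYVDGVEVHNAK,6,6,A,0.18,2.00
mAb1_HC,D280,H2O loss,FNWYVDGVEVHNAK,6,6,B,0.35,3.12
mAb1_HC,M252,oxidation,DTLMISR,4,0,A,3.40,2.25
mAb1_HC,M252,oxidation,DTLMISR,4,0,B,2.81,5.04
mAb1_HC,M252,oxidation,DTLMISR,4,3,A,5.93,3.19
mAb1_HC,M252,oxidation,DTLMISR,4,3,B,4.94,2.19
mAb1_HC,M252,oxidation,DTLMISR,4,6,A,5.82,2.20
mAb1_HC,M252,oxidation,DTLMISR,4,6,B,5.59,1.84
mAb3_LC,M4,oxidation,DIQMTQSPSSLSASVGDR,4,0,A,1.79,7.23
mAb3_LC,M4,oxidation,DIQMTQSPSSLSASVGDR,4,0,B,0.06,19.61
mAb3_LC,M4,oxidation,DIQMTQSPSSLSASVGDR,4,3,A,2.46,6.82
mAb3_LC,M4,oxidation,DIQMTQSPSSLSASVGDR,4,3,B,0.09,5.89
mAb3_LC,M4,oxidation,DIQMTQSPSSLSASVGDR,4,6,A,1.77,3.75
mAb3_LC,M4,oxidation,DIQMTQSPSSLSASVGDR,4,6,B,0.09,8.60
mAb3_LC,M48,oxidation,LLMYISR,3,0,A,0.45,7.93
mAb3_LC,M48,oxidation,LLMYISR,3,3,A,0.59,6.12
mAb3_LC,M48,oxidation,LLMYISR,3,6,A,0.582,1.70
mAb1_HC,M428,oxidation,WQQGNVFSCSVMHEALHNHYTQK,12,0,A,1.87,6.04
mAb1_HC,M428,oxidation,WQQGNVFSCSVMHEALHNHYTQK,12,0,B,1.16,6.90
mAb1_HC,M428,oxidation,WQQGNVFSCSVMHEALHNHYTQK,12,3,A,2.35,4.69
mAb1_HC,M428,oxidation,WQQGNVFSCSVMHEALHNHYTQK,12,3,B,1.91,3.68
mAb1_HC,M428,oxidation,WQQGNVFSCSVMHEALHNHYTQK,12,6,A,2.38,12.20
mAb1_HC,M428,oxidation,WQQGNVFSCSVMHEALHNHYTQK,12,6,B,2.27,3.21
mAb2_LC,W50,oxidation,LLIYWASTR,5,0,A,0.18,2.80
mAb2_LC,W50,oxidation,LLIYWASTR,5,0,B,0.24,5.37
mAb2_LC,W50,oxidation,LLIYWASTR,5,3,A,0.55,0.38
mAb2_LC,W50,oxidation,LLIYWASTR,5,3,B,0.70,8.58
mAb2_LC,W50,oxidation,LLIYWASTR,5,6,A,0.87,7.23
mAb2_LC,W50,oxidation,LLIYWASTR,5,6,B,1.01,4.93
mAb1_LC,M4,oxidation,DVVMTQSPLSLPVTLGQPASISCR,4,0,A,1.85,2.51
mAb1_LC,M4,oxidation,DVVMTQSPLSLPVTLGQPASISCR,4,0,B,0.56,4.53
mAb1_LC,M4,oxidation,DVVMTQSPLSLPVTLGQPASISCR,4,3,A,5.04,1.96
mAb1_LC,M4,oxidation,DVVMTQSPLSLPVTLGQPASISCR,4,3,B,3.26,1.56
mAb1_LC,M4,oxidation,DVVMTQSPLSLPVTLGQPASISCR,4,6,A,5.20,9.02
mAb1_LC,M4,oxidation,DVVMTQSPLSLPVTLGQPASISCR,4,6,B,3.63,1.15
mAb2_HC,W33,oxolactone,ASGYTFTSYWMQWVR,10,0,A,0.20,3.94
mAb2_HC,W33,oxolactone,ASGYTFTSYWMQWVR,10,0,B,0.35,4.06
mAb2_HC,W33,oxolactone,ASGYTFTSYWMQWVR,10,3,A,3.97,6.33
mAb2_HC,W33,oxolactone,ASGYTFTSYWMQWVR,10,3,B,6.89,20.13
mAb2_HC,W33,oxolactone,ASGYTFTSYWMQWVR,10,6,A,6.18,0.64
mAb2_HC,W33,oxolactone,ASGYTFTSYWMQWVR,10,6,B,12.17,5.54
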