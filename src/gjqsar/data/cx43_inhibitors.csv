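cid,name,species,assay,neg_log_e_ic50,SpMin5_Bhm,SpMax3_Bhi,minHBd,pred_docking,pred_qsar,pred_3dqsar,o3a_score,exclusion_flags
1598,2-APB,rat,patch_clamp,4.29,1.08,3.51,0.47,,4.68,,,organoboron
3371,FFA,rat,patch_clamp,4.40,1.13,3.36,0.48,4.47,3.60,4.42,1177,
4037,MFA,human,metabolic_communication,3.58,1.14,3.23,0.33,4.19,3.66,3.41,1124,
4046,Mefloquine,human,metabolic_communication,5.05,1.28,3.63,0.28,4.60,5.50,5.19,1267,
8129,Heptanol,human,metabolic_communication,2.66,0.81,3.11,0.67,2.88,2.64,3.83,598,
10114,18beta-GA,human,metabolic_communication,5.70,1.63,3.75,0.13,5.71,5.36,5.75,1428,
18818,Sabinene,rat,patch_clamp,4.42,1.21,3.13,0.00,4.37,4.60,4.51,701,
22311,d-Limonene,rat,patch_clamp,4.52,1.12,3.09,0.00,4.18,4.84,4.35,773,
73398,18alpha-GA,human,metabolic_communication,5.82,1.63,3.75,0.13,6.05,5.36,5.90,1400,
441074,Quinidine,human,metabolic_communication,3.40,1.42,3.52,0.20,3.97,4.72,3.31,1136,
636403,CBNX,human,metabolic_communication,3.68,1.69,3.76,0.36,5.09,3.81,3.37,1502,
2724385,Digoxin,human,metabolic_communication,6.87,1.82,3.84,-0.19,,6.77,,,no_clear_3d_structure
6857793,DGBA,human,metabolic_communication,4.88,1.80,3.74,0.03,,5.02,,,no_clear_3d_structure
11240513,alpha-Pinene,rat,patch_clamp,4.91,1.14,3.05,0.00,4.21,4.51,4.49,719,
12303902,alpha-Copaene,rat,patch_clamp,5.85,1.37,3.40,0.00,4.95,5.38,5.06,890,
54676038,Dicumarol,rat,metabolic_communication,5.52,1.13,3.63,0.44,4.82,5.30,5.57,1286,
54678486,Warfarin,rat,metabolic_communication,5.12,1.26,3.61,0.38,5.18,4.94,5.38,1145,
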