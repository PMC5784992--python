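cell_line,type,tissue,n_active,auc_loo,auc_kfold
AG1523,Fibroblast,Fibroblast,25,0.971,0.971
BJ,Foreskin fibroblast,Foreskin,37,0.889,0.862
CRL-7065,Fibroblast,Skin,9,0.926,0.927
Detroit 551,Embryonic skin,Skin,30,0.962,0.962
HaCaT,Keratinocyte,Skin,218,0.978,0.978
HASMC,Aortic smooth muscle,Muscle,26,0.999,0.999
HEK293,Embryonic kidney fibroblast,Kidney,711,0.922,0.921
HEL 299,Fibroblast,Lung,3,0.889,0.891
HFF,Foreskin fibroblast,Skin,171,0.974,0.974
HFL1,Human foetal lung fibroblast,Lung,3,1.000,1.000
HMEC,Microvascular endothelial cell,Breast,64,0.948,0.950
HS27,Fibroblast,Skin,40,0.971,0.972
HUVEC,Umbilical vein endothelial cell,Endothelium,999,0.958,0.958
IMR-90,Embryonic lung fibroblast,Lung,14,0.860,0.862
MRC5,Embryonic lung fibroblast,Lung,392,0.921,0.920
MT2,Lymphocyte (HTLV-1 producing cell line),Blood,93,0.968,0.969
NFF,Fibroblast,Skin,57,0.978,0.978
NHDF,Fibroblast,Skin,51,0.947,0.941
PBMC,Peripheral blood mononuclear cell,Blood,1194,0.973,0.972
PrEC,Prostate epithelial cell,Prostate,4,0.802,0.804
RPTEC,Renal proximal tubule epithelial cells,Kidney,8,0.998,0.998
SKW 6.4,B lymphocyte; Epstein-Barr virus (EBV) transformed,"Haematopoietic, lymphoid tissue",39,1.000,1.000
TERT-RPE1,Retinal pigmented epithelial cell,Retina,10,0.903,0.904
WI-38,Embryonic lung fibroblast,Lung,150,0.939,0.939
WI-38 VA13,Embryonic lung fibroblast,Lung,6,0.965,0.965
WIL2,Lymphoblastoid cell,"Haematopoietic, lymphoid tissue",31,1.000,1.000
WIL2-NS,Lymphoblastoid cell,"Haematopoietic, lymphoid tissue",44,0.961,0.953
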