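dataset,cancer,platform_name,n_cells_after_qc,n_tumor_samples,n_normal_samples,n_cells_tumor,n_cells_normal,has_age
Gastric,Gastric cancer,10x Genomics,44684,8,8,30626,14058,yes
melanoma_GSE115978,Melanoma,Smart-seq2,5910,31,0,5910,0,yes
melanoma_GSE72056,Melanoma,Smart-seq2,3883,19,0,3883,0,yes
Uveal,Uveal melanoma,10x Genomics,116752,11,0,116752,0,yes
BC_Qian,Breast cancer,5prime-scRNA-seq,44024,14,0,44024,0,yes
CRC_Qian,CRC,10x Genomics,44684,7,7,30626,14058,yes
HCC,HCC,10x Genomics,9581,19,0,9581,0,yes
HNSCC,HNSCC,Smart-seq2,4849,18,0,4849,0,no
LC_Qian,Lung cancer,10x Genomics,93575,7,7,66309,27266,yes
OVC_Qian,Ovarian cancer,10x Genomics,45114,5,2,34469,10645,yes
Bladder,Bladder cancer,10x Genomics,4077,2,0,4077,0,no
Kidney,Kidney,10x Genomics,72394,11,11,22476,49918,yes
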