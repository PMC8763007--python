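cell_type,CRC_Qian,LC_Qian,OVC_Qian,Kidney,Gastric
B,3309,387,53,514,3623
DC,0,540,0,0,0
EC,688,2383,806,2870,615
Fibroblast,3329,0,5689,554,1173
Mast cell,261,230,0,35,97
Myeloid,1209,10075,1599,1624,1191
T,1694,9046,1072,3419,8672
Alveolar,0,3555,0,0,0
Enteric glia,691,0,0,0,0
Epithelial,2324,378,238,39233,2937
Myofibroblast,553,672,1188,1669,0
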