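cell_type,CRC_Qian,LC_Qian,BC_Qian,OVC_Qian,Bladder,Kidney,Gastric,HCC,Uveal,melanoma_GSE115978,melanoma_GSE72056,HNSCC
B,3889,7590,4566,790,0,369,2388,1160,72899,963,741,523
DC,0,1353,166,0,0,0,0,0,0,24,16,0
EC,1831,1340,2568,1113,142,1413,2309,1089,525,74,75,242
Fibroblast,2114,0,6463,6934,139,124,1836,157,6720,0,90,659
Mast cell,440,970,367,0,0,464,295,0,0,0,0,123
Myeloid,2988,10805,3597,4963,0,5150,3022,826,10030,263,130,150
T,6635,29422,14877,5055,0,10981,10045,2850,13763,3584,2027,1200
Alveolar,0,1465,0,0,0,0,0,0,0,0,0,0
Enteric glia,124,0,0,0,0,0,0,0,0,0,0,0
Epithelial,10590,11571,10056,15144,3726,3412,7426,2658,12815,1002,804,1306
Myofibroblast,2015,1793,1364,470,70,563,0,841,0,0,0,646
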