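# MACCS key numbers (1-based) per molecule, computed with OpenBabel 3.1.0
# (obabel -ofps -xfMACCS); an independent reference implementation.
c1ccccc1	162,163,165
c1ccccc1[N+](=O)[O-]	24,49,56,63,70,71,94,102,119,122,124,130,133,135,148,156,158,159,161,162,163,164,165
CCO	82,109,114,139,153,155,157,160,164
CC(=O)O	123,139,154,157,159,160,164
c1ccncc1	65,98,121,137,161,162,163,165
C1CCCCC1	118,128,129,147,163,165
CC(=O)Nc1ccc(O)cc1	92,110,113,117,127,131,133,135,139,143,151,152,154,156,157,158,159,160,161,162,163,164,165
c1ccsc1	36,83,88,96,137,162,165
c1ccoc1	57,83,96,137,162,164,165
CCN(CC)CC	85,86,100,114,116,122,138,141,148,149,153,155,158,160,161
CC(C)Cc1ccc(C)cc1	74,115,141,149,155,160,162,163,165
NS(=O)(=O)c1ccccc1	32,33,51,55,58,59,60,61,64,67,69,73,81,84,88,94,102,106,112,117,124,130,136,148,151,156,159,161,162,163,164,165
N#Cc1ccccc1	41,161,162,163,165
Clc1ccccc1	87,103,107,134,162,163,165
OCC(O)CO	53,54,72,82,89,90,104,109,131,132,138,139,146,152,153,155,157,159,164
CC#N	41,160,161
Cc1ccc(N)cc1	84,133,135,151,156,158,160,161,162,163,165
CNC(=O)c1ccccc1	92,93,110,117,151,154,156,158,160,161,162,163,164,165
CSC	74,86,88,93,149,160
O=C(O)c1ccccc1O	53,89,113,123,127,131,139,143,144,146,150,152,154,157,159,162,163,164,165
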