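# Synthetic training pool: small neutral drug-like molecules,
# all within the codec's representable subset (verified by tests).
CCO
CC(=O)O
NCC(=O)O
CC(N)C(=O)O
NC(N)=O
C1CCCCC1
C1CCOC1
C1COCCN1
C1CCNCC1
C1CNCCN1
c1ccccc1
Cc1ccccc1
Oc1ccccc1
Nc1ccccc1
Clc1ccccc1
c1ccncc1
c1cncnc1
c1cc[nH]c1
c1ccoc1
c1ccsc1
c1cnc[nH]1
c1ccc2ccccc2c1
c1ccc2[nH]ccc2c1
c1ccc2ncccc2c1
CC(=O)Oc1ccccc1C(=O)O
CC(=O)Nc1ccc(O)cc1
CC(C)Cc1ccc(cc1)C(C)C(=O)O
O=C(O)c1ccccc1O
NC(=O)c1ccccc1
CC(=O)Nc1ccccc1
Nc1ccc(cc1)S(N)(=O)=O
CCOC(=O)c1ccc(N)cc1
CCN(CC)CCOC(=O)c1ccc(N)cc1
CCN(CC)CC(=O)Nc1c(C)cccc1C
CN1CCCC1c1cccnc1
COc1cc(C=O)ccc1O
O=CC=Cc1ccccc1
NCCc1ccc(O)c(O)c1
NCCc1c[nH]c2ccc(O)cc12
CC(=O)NCCc1c[nH]c2ccc(OC)cc12
CCC1(CC)C(=O)NC(=O)NC1=O
O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1
O=c1cc[nH]c(=O)[nH]1
Nc1ncnc2[nH]cnc12
Cn1cnc2c1c(=O)n(C)c(=O)n2C
CC(C)C1CCC(C)CC1O
CC1(C)C2CCC1(C)C(=O)C2
CC(=C)C1CCC(C)=CC1
CC(C)NCC(O)COc1cccc2ccccc12
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
COc1ccc2cc(ccc2c1)C(C)C(=O)O
CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
FC(F)(F)c1ccc(OC(CCNC)c2ccccc2)cc1
CSCCC(N)C(=O)O
OCC(O)C(O)C(O)C(O)CO
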