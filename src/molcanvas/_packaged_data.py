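"""Packaged fixture molecules.

~120 drug-like SMILES restricted to MOSES-style chemistry (C, N, O, S, F,
Cl, Br; single-digit ring closures; no charges, isotopes or stereo).
Every entry parses under the chemistry adapter and round-trips through
the SELFIES and DeepSMILES codecs (enforced by the test suite).
"""

PACKAGED_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC(=O)Nc1ccc(O)cc1",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "CN1CCCC1c1cccnc1",
    "CCOC(=O)c1ccc(N)cc1",
    "CCn1nnnc1SCC(=O)N1CCc2ccccc21",
    "O=C(NCc1cccs1)Nc1ccc(F)cc1",
    "O=C(O)c1ccccc1O",
    "Nc1ccc(S(=O)(=O)N)cc1",
    "Oc1ccc(Cl)cc1",
    "CC(N)Cc1ccccc1",
    "CNC(C)Cc1ccccc1",
    "NC(=O)c1ccccc1",
    "Nc1ccccc1C(=O)O",
    "COc1ccc(CCN)cc1OC",
    "NCCc1ccc(O)c(O)c1",
    "NCCc1c[nH]c2ccccc12",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",
    "CN(C)CCc1c[nH]c2ccccc12",
    "OCC(O)COc1ccccc1",
    "CC(C)NCC(O)COc1ccccc1",
    "COc1ccccc1OCCN",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1",
    "Oc1ccc2ccccc2c1",
    "O=C1CCCCC1",
    "O=C1CCCN1",
    "O=C1CCCCN1",
    "O=C1NC(=O)NC(=O)C1",
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
    "CC(=O)c1ccccc1",
    "COC(=O)c1ccccc1N",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CN1CCN(c2ccccc2)CC1",
    "c1ccc(N2CCNCC2)cc1",
    "O=S(=O)(N)c1ccc(Cl)cc1",
    "Clc1ccccc1Cl",
    "Fc1ccc(F)cc1",
    "FC(F)(F)c1ccccc1",
    "Brc1ccccc1",
    "Clc1ccc2c(c1)CCN2",
    "CC(C)(C)NCC(O)c1ccc(O)c(O)c1",
    "CC(C)(C)NCC(O)c1ccc(O)cc1",
    "CNCC(O)c1ccc(O)c(O)c1",
    "CC(C)Nc1ccccc1",
    "CCOc1ccccc1",
    "COc1ccc(C=O)cc1",
    "COc1cc(C=O)ccc1O",
    "O=Cc1ccccc1",
    "OCc1ccccc1",
    "NCc1ccccc1",
    "OCCc1ccccc1",
    "O=C(O)Cc1ccccc1",
    "O=C(O)CCc1ccccc1",
    "CC(c1ccccc1)c1ccccc1",
    "O=C(c1ccccc1)c1ccccc1",
    "Oc1ccccc1O",
    "Oc1ccc(O)cc1",
    "Nc1ccc(O)cc1",
    "Nc1ccc(Cl)cc1",
    "Nc1ccc(F)cc1",
    "Nc1ccc(Br)cc1",
    "CSc1ccccc1",
    "CS(=O)c1ccccc1",
    "CS(=O)(=O)c1ccccc1",
    "O=S(=O)(c1ccccc1)N1CCCC1",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc(Oc2ccccc2)cc1",
    "c1ccc(Cc2ccccc2)cc1",
    "c1ccc(Sc2ccccc2)cc1",
    "c1ccc(Nc2ccccc2)cc1",
    "c1ccc2c(c1)CCCC2",
    "c1ccc2c(c1)CCNC2",
    "c1ccc2c(c1)OCO2",
    "c1ccc2c(c1)ncs2",
    "c1ccc2[nH]cnc2c1",
    "c1ccc2oc(N)nc2c1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "c1cnc[nH]1",
    "c1cn[nH]c1",
    "Cc1ccccc1C",
    "Cc1ccc(C)cc1",
    "Cc1cccc(C)c1N",
    "Cc1ccc(S(N)(=O)=O)cc1",
    "CC(=O)N1CCN(c2ccc(OC)cc2)CC1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "O=C(Nc1ccc(Cl)cc1)c1ccccc1O",
    "COc1ccc(N)cc1",
    "COc1ccc(NC(C)=O)cc1",
    "CCOC(=O)CC(C)=O",
    "CC(=O)CC(=O)C",
    "CCOC(=O)c1cncn1C",
    "N#Cc1ccccc1",
    "N#CCc1ccccc1",
    "O=C(O)c1cccnc1",
    "O=C(O)c1ccncc1",
    "Cc1ncc(CO)c(C=O)c1O",
    "OCC1OC(O)C(O)C(O)C1O",
    "CN(C)c1ccc(C=O)cc1",
    "CN(C)CCCN",
    "NCCCNCCCCN",
    "O=C(CCl)Nc1ccccc1",
    "ClCC(=O)N(C)c1ccccc1",
    "O=C(CBr)c1ccccc1",
    "CC(O)c1ccccc1",
    "CC(N)c1ccccc1",
    "OC(CCl)c1ccccc1",
    "C#Cc1ccccc1",
    "C=Cc1ccccc1",
    "CC=Cc1ccccc1",
    "CC(C)=CCCC(C)=CCO",
    "CC(C)CCCC(C)CCCC(C)CCCC(C)C",
    "O=c1cc(-c2ccccc2)oc2ccccc12",
    "O=c1ccc2ccccc2o1",
    "Cc1cc(=O)oc2cc(O)ccc12",
    "O=c1[nH]c(=O)c2[nH]cnc2[nH]1",
    "Nc1ncnc2[nH]cnc12",
    "Nc1nc(O)c2ncn(C)c2n1",
)
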