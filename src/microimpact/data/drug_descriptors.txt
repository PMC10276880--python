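MolWt
HeavyAtomMolWt
ExactMolWt
NumValenceElectrons
MolLogP
MolMR
TPSA
LabuteASA
NumHDonors
NumHAcceptors
NumRotatableBonds
NumHeteroatoms
NHOHCount
NOCount
RingCount
NumAromaticRings
NumAliphaticRings
NumSaturatedRings
FractionCSP3
HeavyAtomCount
BalabanJ
BertzCT
HallKierAlpha
MaxPartialCharge
MinPartialCharge
MaxAbsPartialCharge
MinAbsPartialCharge
MaxEStateIndex
MinEStateIndex
MaxAbsEStateIndex
MinAbsEStateIndex
Kappa1
Kappa2
Kappa3
Chi0
Chi0n
Chi0v
Chi1
Chi1n
Chi1v
Chi2n
Chi2v
Chi3n
Chi3v
Chi4n
Chi4v
PEOE_VSA1
PEOE_VSA2
PEOE_VSA3
PEOE_VSA4
PEOE_VSA5
PEOE_VSA6
PEOE_VSA7
PEOE_VSA8
PEOE_VSA9
PEOE_VSA10
PEOE_VSA11
PEOE_VSA12
PEOE_VSA13
PEOE_VSA14
SlogP_VSA1
SlogP_VSA2
SlogP_VSA3
SlogP_VSA4
SlogP_VSA5
SlogP_VSA6
SlogP_VSA7
SlogP_VSA8
SlogP_VSA9
SlogP_VSA10
SlogP_VSA11
SlogP_VSA12
SMR_VSA1
SMR_VSA2
SMR_VSA3
SMR_VSA4
SMR_VSA5
SMR_VSA6
SMR_VSA7
SMR_VSA8
SMR_VSA9
SMR_VSA10
VSA_EState1
VSA_EState2
VSA_EState3
VSA_EState4
VSA_EState5
VSA_EState6
VSA_EState7
VSA_EState8
VSA_EState9
VSA_EState10
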