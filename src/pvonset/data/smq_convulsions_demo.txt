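# Demo convulsions term list (synthetic subset for examples and tests).
# This is NOT the licensed MedDRA SMQ; supply your own file for real
# analyses (the narrow-scope convulsions SMQ, code 20000079, has 101 PTs).
code: 20000079
scope: narrow
Seizure
Generalised tonic-clonic seizure
Tonic convulsion
Clonic convulsion
Myoclonic epilepsy
Status epilepticus
Epilepsy
Partial seizures
Atonic seizures
Convulsion in childhood
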