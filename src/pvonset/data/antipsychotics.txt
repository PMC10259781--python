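# Antipsychotic generic names used for the polypharmacy covariate
# (editable; clozapine itself is excluded by the polypharmacy rule).
clozapine
risperidone
paliperidone
olanzapine
quetiapine
aripiprazole
brexpiprazole
blonanserin
perospirone
lurasidone
asenapine
haloperidol
chlorpromazine
levomepromazine
zotepine
sulpiride
fluphenazine
bromperidol
pimozide
oxypertine
nemonapride
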