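# Antiepileptic agents counted as concomitant anticonvulsant therapy.
sodium valproate
carbamazepine
lamotrigine
clonazepam
diazepam
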