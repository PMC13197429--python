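# misspelling	correction (case-insensitive token match)
automatims	automatisms
automatsims	automatisms
siezure	seizure
seizue	seizure
sezure	seizure
tonic-clonc	tonic-clonic
clonc	clonic
deja-vu	deja vu
epigastic	epigastric
nystagmous	nystagmus
paresthesia	paraesthesia
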