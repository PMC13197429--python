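# token	expansion (applied to whitespace tokens after punctuation-insensitive match)
LOC	loss of consciousness
GTC	generalized tonic-clonic
GTCS	generalized tonic-clonic seizure
FBTC	focal to bilateral tonic-clonic
CPS	complex partial seizure
SPS	simple partial seizure
EEG	electroencephalogram
L	left
R	right
b/l	bilateral
w/	with
w/o	without
sec	seconds
min	minutes
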