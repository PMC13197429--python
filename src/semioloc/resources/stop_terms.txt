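# uninformative words removed from semiology descriptions (one per line,
# case-insensitive token match). Minimal default list; override per corpus.
patient
patients
pt
reported
reportedly
reports
describes
described
presents
presented
episode
episodes
history
hx
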