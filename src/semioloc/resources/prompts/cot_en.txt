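Solve the problem in step by step manner. In addition to the likelihood dictionary, include the keys "Reasoning" and "Sources" in your JSON answer.
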