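Given the seizure semiology below, estimate the likelihood (in percent) that the seizure onset zone lies in each of the following seven brain regions: {region_list}.
Return your answer strictly as a JSON dictionary whose keys are exactly these seven region names and whose values are likelihood percentages.
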