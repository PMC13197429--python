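# SYNTHETIC PLACEHOLDER expert reasoning templates for few-shot CoT exemplars.
# One template per line; "{region}" is replaced by the exemplar's ground-truth
# region. These are generic stand-ins, not clinician-authored text: replace with
# expert-curated reasoning before any real evaluation.
The described manifestations are classical localizing signs; their onset pattern and spread are most consistent with an origin in the {region}, so the bulk of the likelihood is assigned there.
Step 1: identify the leading symptom. Step 2: map it to its canonical generator. Step 3: the generator for this presentation lies in the {region}, which therefore receives the highest likelihood.
Considering the sequence and laterality of the signs, networks within the {region} are the most plausible seizure onset zone; neighbouring regions retain small residual likelihoods.
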