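请逐步推理解决该问题。除了可能性字典之外，请在 JSON 答案中包含 "Reasoning" 和 "Sources" 两个键。
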