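根据下面的癫痫发作症状描述，估计发作起始区位于以下七个脑区中每一个的可能性（百分比）：{region_list}。
请严格以 JSON 字典格式回答，键必须恰好是这七个脑区名称，值为可能性百分比。
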