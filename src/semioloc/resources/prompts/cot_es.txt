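Resuelva el problema paso a paso. Además del diccionario de probabilidades, incluya las claves "Reasoning" y "Sources" en su respuesta JSON.
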