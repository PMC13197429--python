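Résolvez le problème étape par étape. En plus du dictionnaire de probabilités, incluez les clés "Reasoning" et "Sources" dans votre réponse JSON.
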