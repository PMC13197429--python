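À partir de la sémiologie de crise ci-dessous, estimez la probabilité (en pourcentage) que la zone de départ des crises se situe dans chacune des sept régions cérébrales suivantes : {region_list}.
Répondez strictement sous la forme d'un dictionnaire JSON dont les clés sont exactement ces sept noms de régions et dont les valeurs sont des pourcentages de probabilité.
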