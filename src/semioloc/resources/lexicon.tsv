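# language	surface form	canonical region (lookup is case- and diacritic-insensitive)
en	Temporal Lobe	Temporal Lobe
en	Frontal Lobe	Frontal Lobe
en	Cingulate Gyrus	Cingulate Gyrus
en	Cingulate Cortex	Cingulate Gyrus
en	Parietal Lobe	Parietal Lobe
en	Occipital Lobe	Occipital Lobe
en	Insula	Insula
en	Insular Cortex	Insula
en	Hypothalamus	Hypothalamus
fr	lobe temporal	Temporal Lobe
fr	lobe frontal	Frontal Lobe
fr	gyrus cingulaire	Cingulate Gyrus
fr	cortex cingulaire	Cingulate Gyrus
fr	lobe pariétal	Parietal Lobe
fr	lobe occipital	Occipital Lobe
fr	insula	Insula
fr	cortex insulaire	Insula
fr	hypothalamus	Hypothalamus
es	lóbulo temporal	Temporal Lobe
es	lóbulo frontal	Frontal Lobe
es	giro cingulado	Cingulate Gyrus
es	circunvolución del cíngulo	Cingulate Gyrus
es	lóbulo parietal	Parietal Lobe
es	lóbulo occipital	Occipital Lobe
es	ínsula	Insula
es	corteza insular	Insula
es	hipotálamo	Hypothalamus
zh	颞叶	Temporal Lobe
zh	额叶	Frontal Lobe
zh	扣带回	Cingulate Gyrus
zh	顶叶	Parietal Lobe
zh	枕叶	Occipital Lobe
zh	岛叶	Insula
zh	脑岛	Insula
zh	下丘脑	Hypothalamus
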