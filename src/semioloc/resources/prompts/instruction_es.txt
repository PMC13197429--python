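A partir de la semiología de la crisis descrita abajo, estime la probabilidad (en porcentaje) de que la zona de inicio de las crisis se encuentre en cada una de las siete regiones cerebrales siguientes: {region_list}.
Responda estrictamente como un diccionario JSON cuyas claves sean exactamente estos siete nombres de regiones y cuyos valores sean porcentajes de probabilidad.
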