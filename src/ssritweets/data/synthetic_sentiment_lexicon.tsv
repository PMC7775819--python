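word	polarity
bueno	positive
buena	positive
bien	positive
amor	positive
gracias	positive
excelente	positive
maravilloso	positive
perfecto	positive
estupendo	positive
encanta	positive
malo	negative
mala	negative
mal	negative
odio	negative
horrible	negative
terrible	negative
fatal	negative
peor	negative
desastre	negative
asqueroso	negative
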