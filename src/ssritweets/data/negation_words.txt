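no
nada
nadie
nunca
jamás
ni
tampoco
sin
ninguno
ninguna
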