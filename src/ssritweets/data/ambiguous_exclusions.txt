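Essential
Motivan
Estar
Traviata
Pondera
Recital
Emergen
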