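wavelength_nm,value
380,0.0004
390,0.0015
400,0.0045
410,0.0093
420,0.0175
430,0.0273
440,0.0379
450,0.0468
460,0.0600
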