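analyte,concentration_ug_per_mL
neochlorogenic acid,7.7
chlorogenic acid,96
forsythoside A,296
isochlorogenic acid A,65
isochlorogenic acid C,15.2
phillyrin,27.5
arctiin,113
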