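wavelength_nm,analyte,mean_f,rsd_pct
237,phillyrin,0.838,0.41
237,arctiin,0.868,0.13
327,neochlorogenic acid,2.182,0.17
327,chlorogenic acid,1.613,0.06
327,isochlorogenic acid A,1.566,0.06
327,isochlorogenic acid C,1.798,0.23
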