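wavelength_nm,analyte,replicate,f
237,phillyrin,1,0.832
237,phillyrin,2,0.836
237,phillyrin,3,0.838
237,phillyrin,4,0.841
237,phillyrin,5,0.840
237,phillyrin,6,0.838
237,arctiin,1,0.867
237,arctiin,2,0.869
237,arctiin,3,0.867
237,arctiin,4,0.867
237,arctiin,5,0.869
237,arctiin,6,0.867
327,neochlorogenic acid,1,2.179
327,neochlorogenic acid,2,2.185
327,neochlorogenic acid,3,2.178
327,neochlorogenic acid,4,2.181
327,neochlorogenic acid,5,2.181
327,neochlorogenic acid,6,2.187
327,chlorogenic acid,1,1.613
327,chlorogenic acid,2,1.614
327,chlorogenic acid,3,1.613
327,chlorogenic acid,4,1.611
327,chlorogenic acid,5,1.614
327,chlorogenic acid,6,1.614
327,isochlorogenic acid A,1,1.567
327,isochlorogenic acid A,2,1.567
327,isochlorogenic acid A,3,1.566
327,isochlorogenic acid A,4,1.564
327,isochlorogenic acid A,5,1.566
327,isochlorogenic acid A,6,1.566
327,isochlorogenic acid C,1,1.793
327,isochlorogenic acid C,2,1.800
327,isochlorogenic acid C,3,1.796
327,isochlorogenic acid C,4,1.803
327,isochlorogenic acid C,5,1.802
327,isochlorogenic acid C,6,1.795
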