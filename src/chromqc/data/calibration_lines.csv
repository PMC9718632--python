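wavelength_nm,analyte,slope,intercept,r,linear_low_ug,linear_high_ug
237,forsythoside A,26.30,0.073,0.9995,0.1776,2.96
237,phillyrin,21.89,0.024,0.9995,0.0165,0.275
237,arctiin,22.68,0.073,0.9995,0.0678,1.130
327,forsythoside A,43.42,0.065,0.9995,0.1776,2.960
327,neochlorogenic acid,94.10,0.048,0.9995,0.00462,0.077
327,chlorogenic acid,70.02,0.027,0.9995,0.0576,0.960
327,isochlorogenic acid A,68.79,-0.420,0.9995,0.039,0.650
327,isochlorogenic acid C,78.88,-0.090,0.9995,0.00912,0.152
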