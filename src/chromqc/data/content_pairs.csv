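wavelength_nm,batch,analyte,esm_mg_g,qams_mg_g,re_printed_pct
237,1,forsythoside A,8.689,,
237,1,phillyrin,0.868,0.862,-0.69
237,1,arctiin,5.077,5.062,-0.30
237,2,forsythoside A,9.311,,
237,2,phillyrin,1.292,1.283,-0.70
237,2,arctiin,4.763,4.748,-0.31
237,3,forsythoside A,8.26,,
237,3,phillyrin,1.146,1.138,-0.70
237,3,arctiin,6.034,6.016,-0.30
237,4,forsythoside A,8.193,,
237,4,phillyrin,1.107,1.099,-0.72
237,4,arctiin,6.024,6.005,-0.32
237,5,forsythoside A,8.224,,
237,5,phillyrin,1.043,1.036,-0.67
237,5,arctiin,6.195,6.176,-0.31
237,6,forsythoside A,9.462,,
237,6,phillyrin,1.125,1.117,-0.71
237,6,arctiin,5.878,5.860,-0.31
237,7,forsythoside A,9.346,,
237,7,phillyrin,1.110,1.103,-0.63
237,7,arctiin,5.653,5.635,-0.32
237,8,forsythoside A,9.316,,
237,8,phillyrin,1.229,1.220,-0.73
237,8,arctiin,5.445,5.428,-0.31
237,9,forsythoside A,8.376,,
237,9,phillyrin,0.993,0.987,-0.60
237,9,arctiin,4.713,4.699,-0.30
237,10,forsythoside A,8.653,,
237,10,phillyrin,1.114,1.107,-0.63
237,10,arctiin,6.257,6.238,-0.30
327,1,forsythoside A,8.603,,
327,1,neochlorogenic acid,0.063,0.063,0.00
327,1,chlorogenic acid,3.633,3.629,-0.11
327,1,isochlorogenic acid A,2.502,2.502,0.00
327,1,isochlorogenic acid C,0.436,0.433,-0.69
327,2,forsythoside A,9.202,,
327,2,neochlorogenic acid,0.070,0.070,0.00
327,2,chlorogenic acid,4.283,4.279,-0.09
327,2,isochlorogenic acid A,2.349,2.349,0.00
327,2,isochlorogenic acid C,0.540,0.536,-0.74
327,3,forsythoside A,8.165,,
327,3,neochlorogenic acid,0.095,0.095,0.00
327,3,chlorogenic acid,4.438,4.433,-0.11
327,3,isochlorogenic acid A,2.871,2.872,0.03
327,3,isochlorogenic acid C,0.669,0.665,-0.60
327,4,forsythoside A,8.082,,
327,4,neochlorogenic acid,0.094,0.094,0.00
327,4,chlorogenic acid,4.590,4.585,-0.11
327,4,isochlorogenic acid A,2.760,2.761,0.04
327,4,isochlorogenic acid C,0.685,0.680,-0.73
327,5,forsythoside A,8.133,,
327,5,neochlorogenic acid,0.093,0.094,1.08
327,5,chlorogenic acid,4.360,4.355,-0.11
327,5,isochlorogenic acid A,2.828,2.828,0.00
327,5,isochlorogenic acid C,0.691,0.687,-0.58
327,6,forsythoside A,9.424,,
327,6,neochlorogenic acid,0.087,0.087,0.00
327,6,chlorogenic acid,4.305,4.301,-0.09
327,6,isochlorogenic acid A,2.792,2.792,0.00
327,6,isochlorogenic acid C,0.616,0.612,-0.65
327,7,forsythoside A,9.300,,
327,7,neochlorogenic acid,0.086,0.086,0.00
327,7,chlorogenic acid,4.198,4.194,-0.10
327,7,isochlorogenic acid A,2.753,2.753,0.00
327,7,isochlorogenic acid C,0.604,0.599,-0.83
327,8,forsythoside A,9.234,,
327,8,neochlorogenic acid,0.086,0.086,0.00
327,8,chlorogenic acid,4.389,4.384,-0.11
327,8,isochlorogenic acid A,2.589,2.590,0.04
327,8,isochlorogenic acid C,0.642,0.638,-0.62
327,9,forsythoside A,8.317,,
327,9,neochlorogenic acid,0.064,0.064,0.00
327,9,chlorogenic acid,3.816,3.812,-0.10
327,9,isochlorogenic acid A,2.342,2.343,0.04
327,9,isochlorogenic acid C,0.485,0.482,-0.62
327,10,forsythoside A,8.549,,
327,10,neochlorogenic acid,0.096,0.096,0.00
327,10,chlorogenic acid,4.394,4.389,-0.11
327,10,isochlorogenic acid A,2.826,2.826,0.00
327,10,isochlorogenic acid C,0.707,0.703,-0.57
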