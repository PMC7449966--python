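# Whole-blood and water absorption coefficients, 10-nm nodes.
# mua_oxyhemoglobin / mua_deoxyhemoglobin: absorption of fully
# oxygenated / deoxygenated whole blood at 150 g/L total hemoglobin,
# assembled from the standard hemoglobin extinction compilations
# (Soret and Q bands, NIR isosbestic region near 800 nm) and smoothed
# with shape-preserving log-space interpolation. mua_water: pure water.
# Units: wavelength_nm in nm, coefficients in 1/cm.
wavelength_nm,mua_oxyhemoglobin,mua_deoxyhemoglobin,mua_water
400,1425,1196,0.00058
410,2500,912,0.00048067
420,2572,700,0.00040483
430,1318,1870,0.00034946
440,549,964,0.0003118
450,336,551,0.00029
460,238,372,0.00027676
470,178,312,0.00026572
480,143,280,0.0002573
490,127,258,0.00025191
500,112,240,0.00025
510,107,234,0.00025851
520,130,240,0.00028299
530,209,279,0.00032308
540,285,291,0.00037899
550,230,302,0.00045
560,175,300,0.0005852
570,240,270,0.00085853
580,198,235,0.0013002
590,74,160,0.00186
600,17.1,80,0.0023
610,9.5,54,0.0025186
620,6.6,40,0.0026823
630,5.1,28.5,0.0028215
640,4.2,23,0.0029771
650,2.6,19.5,0.0032
660,1.9,17.3,0.0035034
670,1.65,15.2,0.0038811
680,1.6,13.8,0.0043757
690,1.7,12.4,0.0050498
700,1.9,11,0.006
710,2.1,9.9,0.0079109
720,2.3,8.8,0.011
730,2.5,7.6,0.015676
740,2.8,7.3,0.022213
750,3,7.5,0.026
760,3.2,7.9,0.025482
770,3.5,7.2,0.024303
780,3.7,6,0.023
790,4,5.1,0.021168
800,4.3,4.5,0.02
810,4.6,4.3,0.022762
820,4.9,4.1,0.028
830,5.2,3.9,0.03273
840,5.4,3.8,0.037943
850,5.7,3.7,0.043
860,5.9,3.6,0.047349
870,6.1,3.5,0.051414
880,6.3,3.5,0.056
890,6.4,3.4,0.061008
900,6.5,3.4,0.068
910,6.5548,3.3927,0.083043
920,6.6,3.3743,0.11
930,6.6624,3.3494,0.1701
940,6.7,3.3231,0.28513
950,6.7,3.3,0.39
960,6.7,3.28,0.43134
970,6.6247,3.26,0.45
980,6.5,3.24,0.44027
990,6.4,3.22,0.40991
1000,6.3,3.2,0.36
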